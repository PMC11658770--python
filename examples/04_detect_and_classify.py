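"""Detect neighbor exchanges in a tracked sequence and classify them.

Generates a synthetic tracked cell sequence with one programmed
tension-feedback T1 and one passive sequence, detects the exchanges from
the adjacency changes, pools the aligned tension trajectories and labels
each event active or passive from its tension-shape vs isogonal-shape
dynamics.
"""

import tigon as tg

for mode in ("active", "passive"):
    seq, truth = tg.generate_t1_sequence(mode, nx=7, ny=7, seed=3)
    events, rosettes = tg.detect_events(seq)
    tg.attach_trajectories(seq, events)
    est = tg.estimate_threshold(events)
    label, scores = tg.classify_active_passive(events[0], seq)
    print(f"{mode} sequence: {len(seq)} frames, "
          f"{len(events)} detected / {len(truth.events)} programmed")
    print(f"  exchange at t* = {events[0].t_star:.2f} min; "
          f"tension at last pre-collapse frame = {est.mean:.4f}")
    print(f"  classified '{label}' "
          f"(tension-shape score {scores['score_tension']:.2f}, "
          f"isogonal score {scores['score_isogonal']:.2f})")
# The active event collapses near sqrt(2) with the tension triangle
# deforming; the passive event collapses at tension 1 with the isogonal
# mode deforming instead.
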