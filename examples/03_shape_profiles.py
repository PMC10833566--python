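"""Predict DNA shape profiles from pentamer context and summarize them.

Uses the synthetic pentamer table (a stand-in fixture with the format and
statistical role of a published shape query table)."""

from regulonml import generate_pentamer_table, shape_vector, summarize

table = generate_pentamer_table(seed=0)
seq = "GCGATATAAGCG"

# Minor groove width: one value per fully covered base (positions 3..L-2).
mgw = shape_vector(seq, table, "MGW")
s = summarize(mgw)
print(f"{seq}: MGW profile over {len(mgw)} positions")
print("  " + " ".join(f"{v:.2f}" for v in mgw))
print(f"  min {s.min:.2f}  mean {s.mean:.2f}  max {s.max:.2f}  range {s.range:.2f} (Angstrom)")

# Roll is an inter-base-pair parameter: one value per covered step, interior
# steps averaged over the two pentamers that predict them.
roll = shape_vector(seq, table, "Roll")
print(f"Roll profile over {len(roll)} steps (degrees):")
print("  " + " ".join(f"{v:.2f}" for v in roll))
# At a matched binding site the 13 parameters x 4 summaries give the 52
# shape features used by the regulon classifier.
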