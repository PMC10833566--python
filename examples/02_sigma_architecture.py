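"""Locate -10/-35 sigma-factor boxes on a promoter and read off the
architecture features (scores, Hamming distances, spacer, AT ratios)."""

from regulonml import default_sigma_pssms, locate_boxes, sigma_feature_block
from regulonml.genome_io import Promoter
from regulonml.sigma import spacer_at_ratio

# A 200 bp promoter (150 bp upstream, 50 bp downstream of the TSS) on a GC
# background, with the sigma-70 consensus boxes planted at -12 (TATAAT) and
# a 17 bp spacer upstream of it (TTGACA).
seq = list("GC" * 100)
m10_start = 150 - 12
seq[m10_start : m10_start + 6] = "TATAAT"
m35_start = m10_start - 17 - 6
seq[m35_start : m35_start + 6] = "TTGACA"
promoter = Promoter(tu_id="demoTU", gene_ids=("demoGene",), tss=150, strand="+",
                    sequence="".join(seq))

pssms = default_sigma_pssms()
placement = locate_boxes(promoter, *pssms["sigma70"])
print(f"-10 box {placement.minus10.site_sequence} at {placement.minus10.offset} "
      f"({placement.minus10.score:.2f} bits)")
print(f"-35 box {placement.minus35.site_sequence} at {placement.minus35.offset} "
      f"({placement.minus35.score:.2f} bits)")
print(f"spacer length {placement.spacer_length} bp, "
      f"best 7-mer AT ratio {spacer_at_ratio(placement):.2f}")
# Both boxes are recovered at the planted offsets; the GC-only spacer has AT
# ratio 0, so this promoter lacks the AT-rich extended -10 signal.

blocks = sigma_feature_block(promoter, pssms)
print(f"{len(blocks)} sigma-factor feature blocks; sigma70 features:")
for key, val in blocks["sigma70"].to_dict().items():
    print(f"  {key:24s} {val}")
# One 9-feature block per sigma factor enters the classifier feature matrix.
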