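"""Reconstruct a multi-strain pan-regulon and relate motif score to
regulatory response.

A synthetic 4-strain family embeds transcription units with a designed
conservation pattern: core TUs (all strains, consensus binding sites),
accessory TUs (some strains), unique TUs (one strain, weakened sites)."""

import numpy as np

from regulonml import (
    SyntheticConfig,
    build_pan_regulon,
    generate_expression_response,
    generate_strain_family,
    map_tu,
    score_response_correlation,
)

family = generate_strain_family(SyntheticConfig(seed=7, n_strains=4))

# Map every TU onto every strain genome by exact substring search (both
# strands) and collect the regulated set per strain.
regulated = {
    strain: {
        tu for tu, seq in family.tu_sequences.items()
        if map_tu(seq, genome, tu_id=tu).status == "unique-match"
    }
    for strain, genome in family.genomes.items()
}
pan = build_pan_regulon(regulated)
print(f"pan-regulon over {len(pan.strains)} strains: "
      f"{len(pan.core)} core, {len(pan.accessory)} accessory, {len(pan.unique)} unique")
for cls, tus in (("core", pan.core), ("accessory", pan.accessory), ("unique", pan.unique)):
    mean_score = np.mean([family.tu_site_scores[t] for t in tus])
    print(f"  {cls:10s} mean planted-site motif score {mean_score:.2f} bits")
# Conserved (core) TUs carry the strongest binding sites, mirroring the
# designed core > accessory > unique strength gradient.

# Expression change is monotone in binding-site strength up to noise.
scores = np.array([family.tu_site_scores[t] for t in sorted(family.tu_sequences)])
scores = np.tile(scores, 50) + np.random.default_rng(1).normal(0, 0.1, 50 * len(scores))
response = generate_expression_response(scores, slope=1.0, noise_sd=0.5, seed=7)
rho, p = score_response_correlation(scores, response)
print(f"Spearman rho(motif score, expression change) = {rho:.3f} (p = {p:.2g})")
# A strong rank correlation: higher motif score, stronger regulatory response.
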