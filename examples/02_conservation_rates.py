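"""Per-residue evolutionary rates from a multiple sequence alignment.

Exposed residues evolve faster than buried ones in every membrane
region; this script computes normalised substitution rates for one
synthetic protein and shows that planted relationship.
"""
import numpy as np

from mprap import SyntheticSpec, normalize_rates
from mprap.synthetic import generate_protein

bundle = generate_protein(SyntheticSpec(seed=1), 2)
rates = normalize_rates(bundle.raw_rates)  # z-scored per protein

truth = bundle.truth
r = rates.rates
rsa = truth["rsa_single"].to_numpy()
print(f"protein {bundle.name}: {len(r)} residues, "
      f"alignment depth {bundle.alignment.depth}")
print(f"Pearson r(rate, RSA) = {np.corrcoef(r, rsa)[0, 1]:.2f}")
for region in ("core", "interface", "nonmembrane"):
    m = truth["region"] == region
    exp = r[m & (rsa >= 25)].mean()
    bur = r[m & (rsa < 25)].mean()
    print(f"{region:<12s} mean rate exposed {exp:+.2f}  buried {bur:+.2f}")

# Rates are unitless z-scores (mean 0, SD 1 per protein). Positive =
# faster-evolving than the protein average; exposed sites should be
# positive and buried sites negative in all three regions.
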