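"""Find protein-protein interface residues from accessibility prediction.

Interface residues are exposed in a single chain but buried in the full
complex. A predictor trained on complexes therefore predicts them as
buried even when given the single chain - so low predicted RSA among
single-chain-exposed residues hints at an interaction surface.
"""
import numpy as np

from mprap import GridSpec, interface_sweep, make_cv_split, predict, train
from mprap.synthetic import (SyntheticSpec, bundle_chain_data,
                             generate_complex, generate_corpus)

spec = SyntheticSpec(n_proteins=10, seed=1)
chains = [bundle_chain_data(b) for b in generate_corpus(spec)]
split = make_cv_split([(c.chain_key, c.family) for c in chains], k=5, seed=1)
model, _ = train(chains, split, GridSpec.coarse(), kernel="rbf", seed=1)

pred_parts, if_parts = [], []
for i in range(3):
    dimer = generate_complex(spec, 100 + i)
    truth_a = dimer.truth[dimer.truth["chain"] == "A"]
    n_if = (truth_a["interface"] == "interface").sum()
    print(f"homodimer {dimer.name}: {len(truth_a)} residues/chain, "
          f"{n_if} planted interface residues")
    cd = bundle_chain_data(dimer)
    values, _ = predict(model, cd.X)
    exposed = truth_a["rsa_single"].to_numpy() > 25.0
    pred_parts.append(values[exposed])
    if_parts.append((truth_a["interface"].to_numpy() == "interface")[exposed])
pred = np.concatenate(pred_parts)
is_if = np.concatenate(if_parts)
print(f"mean predicted RSA: interface {pred[is_if].mean():.1f}%  "
      f"other exposed {pred[~is_if].mean():.1f}%")

curve = interface_sweep(pred, is_if, cutoffs=np.arange(10, 51, 10.0))
print(curve.to_string(index=False))

# interface_fraction_below = recall of interface residues at that
# predicted-RSA cutoff; noninterface_fraction_above = how many ordinary
# exposed residues survive; precision = purity of the flagged set.
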