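"""Use the predictor to flag erroneous structures.

A correct structure agrees with sequence-based accessibility prediction;
a wrong one (here simulated by permuting the observed burial states)
shows near-random agreement. The MCC gap is the quality signal.
"""
import numpy as np

from mprap import GridSpec, binarize, make_cv_split, predict, qa_structure, train
from mprap.synthetic import SyntheticSpec, bundle_chain_data, generate_corpus

spec = SyntheticSpec(n_proteins=10, seed=1)
chains = [bundle_chain_data(b) for b in generate_corpus(spec)]
split = make_cv_split([(c.chain_key, c.family) for c in chains], k=5, seed=1)
model, _ = train(chains, split, GridSpec.coarse(), kernel="rbf", seed=1)

observed, predicted = [], []
for cd in chains:
    _, states = predict(model, cd.X)
    predicted.extend(states)
    observed.extend(binarize(v, 25.0) for v in cd.y_rsa)

intact = qa_structure(observed, predicted)
rng = np.random.default_rng(0)
perm = rng.permutation(len(observed))
decoy = qa_structure([observed[i] for i in perm], predicted)

print(f"intact structures: accuracy={intact.accuracy:.2f} "
      f"MCC={intact.mcc:.2f} suspicious={intact.suspicious}")
print(f"label-permuted decoy: accuracy={decoy.accuracy:.2f} "
      f"MCC={decoy.mcc:.2f} suspicious={decoy.suspicious}")

# A structure is flagged suspicious when observed-vs-predicted MCC falls
# below 0.3 - between the scores of known-retracted (< 0.26) and
# known-correct (> 0.64) membrane-protein structures.
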