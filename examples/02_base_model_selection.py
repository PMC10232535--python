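"""Train and select the source-reaction selectivity model by 10-fold CV.

Generates a synthetic screening campaign (59 records over 11 indoles x
14 alkenes x 25 CCAs, encoded in the 108-dimensional physical-organic
space), cross-validates a zoo of regressors and reports the ranking.
"""

from chirtransfer import (
    RegressorSpec,
    SyntheticSPRConfig,
    encode_dataset,
    rank_algorithms,
)
from chirtransfer.synthetic import generate_descriptor_library, generate_source_domain

cfg = SyntheticSPRConfig(seed=0)
lib = generate_descriptor_library(cfg)
records = generate_source_domain(cfg, lib)
dataset = encode_dataset(records, lib.tables)
print(f"{dataset.n} source records, {dataset.X.shape[1]}-dimensional encoding\n")

specs = [RegressorSpec(name) for name in
         ("linear_svr", "ridge", "lasso", "kernel_svr", "random_forest",
          "gradient_boosting", "k_neighbors")]
print(f"{'algorithm':20s} {'Pearson R':>10s} {'MAE (kcal/mol)':>15s}")
for report in rank_algorithms(dataset, specs, k=10, seed=0):
    r = "undef" if report.pearson_r is None else f"{report.pearson_r:.3f}"
    print(f"{report.spec.algorithm:20s} {r:>10s} {report.mae:>15.3f}")

print(
    "\nHigher Pearson R / lower MAE is better. With a near-linear latent "
    "SPR the linear family (ridge / lasso / linear SVR) tops the table "
    "while trees and k-NN trail — the reason a linear model is the right "
    "base learner for this kind of campaign."
)
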