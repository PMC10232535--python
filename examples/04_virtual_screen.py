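"""Virtual screen of a 360-candidate CCA library with the transfer model.

Enumerates 4 backbones x 90 N-substituents, predicts every candidate's
enantioselectivity in the fixed target substrate context, bins the
distribution and prints the Top-3 — then compares against the naive
baseline (one model pooled over source + target data) by asking where each
model ranks the generator's true best candidate.
"""

from chirtransfer import (
    RegressorSpec,
    ScreeningContext,
    SyntheticSPRConfig,
    bin_distribution,
    encode_dataset,
    enumerate_candidates,
    fit_base,
    fit_naive_pooled,
    fit_transfer,
    pair_table_source,
    screen,
    top_k,
)
from chirtransfer.synthetic import (
    generate_descriptor_library,
    generate_source_domain,
    generate_target_domain,
    make_latent,
    make_perturbation,
    true_candidate_scores,
)

cfg = SyntheticSPRConfig(seed=0)
lib = generate_descriptor_library(cfg)
latent = make_latent(cfg, lib)
perturbation = make_perturbation(cfg, lib)
source = generate_source_domain(cfg, lib, latent)
target = generate_target_domain(cfg, lib, latent, perturbation)

base = fit_base(encode_dataset(source, lib.tables), RegressorSpec("linear_svr"))
transfer = fit_transfer(base, target, lib.tables)

context = ScreeningContext(target[0].indole_id, target[0].alkene_id, 298.15)
candidates = enumerate_candidates(
    lib.backbone_ids, lib.substituent_ids, pair_table_source(lib.candidate_frame)
)
result = screen(transfer, candidates, context, lib.tables)

bins = bin_distribution(result)
print(f"screened {result.n} candidates in context {context.indole_id}/{context.alkene_id}")
print(f"predicted e.e. bins: <40%: {bins[0]}   40-80%: {bins[1]}   >80%: {bins[2]}")
print("\nTop-3 candidates:")
for e in top_k(result, 3):
    print(f"  rank {e.rank}: {e.candidate_id}  ddG {e.ddg_pred:.3f} kcal/mol  ee {e.ee_pred:.1%}")

truth = true_candidate_scores(cfg, lib, latent, perturbation, context)
best = str(truth.idxmax())
naive = fit_naive_pooled(
    encode_dataset(source, lib.tables),
    encode_dataset(target, lib.tables),
    RegressorSpec("linear_svr"),
)
naive_result = screen(naive, candidates, context, lib.tables)


def rank_of(res, cid):
    return next(e.rank for e in res.entries if e.candidate_id == cid)


print(f"\ntrue best candidate (known from the generator): {best}")
print(f"  rank under transfer model: {rank_of(result, best)}")
print(f"  rank under naive pooled model: {rank_of(naive_result, best)}")
print(
    "\nA low transfer-model rank means the corrected SPR puts the truly "
    "best catalyst where a Top-k synthesis campaign would find it; the "
    "naive pooled model blurs the two reactions and buries it."
)
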