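"""Pathway co-regulation networks and decoupling between conditions.

Builds shared-gene-corrected Spearman correlation matrices of pathway
activity profiles in two conditions that differ only in how strongly
pathway latent activities are coupled, thresholds them into networks, and
tests the global coupling difference.
"""

from arscore import (
    GeneratorConfig,
    all_pairs,
    build_network,
    compare_coupling,
    generate,
    standardize_genewise,
)

data = generate(
    GeneratorConfig(
        n_genes=1500,
        n_pathways=30,
        n_samples={"normal": 80, "tumor": 80},
        gamma={"normal": 0.8, "tumor": 0.3},  # tumor pathways are decoupled
        rho_within=0.5,
        delta=0.0,
        seed=0,
    )
)

corr = {}
for condition in ("normal", "tumor"):
    relative = standardize_genewise(data.condition_matrix(condition)).matrix
    corr[condition] = all_pairs(data.sets, relative)
    net = build_network(corr[condition], tau=0.75, sizes=data.sets.sizes())
    print(
        f"{condition}: {corr[condition].n_pairs} pathway pairs evaluated, "
        f"{len(net.edges)} edges at |rho| > 0.75"
    )

result = compare_coupling(corr["normal"], corr["tumor"])  # paired t on |rho|
print(
    f"\ncoupling comparison (normal vs tumor): t = {result.t:.1f}, P = {result.p:.2e}\n"
    "positive t: pathway activity profiles are more tightly correlated in the\n"
    "normal condition - exactly the decoupling the generator planted."
)
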