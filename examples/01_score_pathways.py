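"""Score pathway activity per sample with the AR-score.

Generates a small two-condition dataset, converts intensities to relative
levels, and prints the AR-scores of a shifted pathway and a null pathway in
a few samples from each condition.
"""

from arscore import GeneratorConfig, activity_matrix, generate, standardize_genewise

data = generate(
    GeneratorConfig(
        n_genes=1000,
        n_pathways=20,
        n_samples={"normal": 10, "tumor": 10},
        rho_within=0.4,
        gamma=0.0,
        differential_pathways=[0],
        delta=1.5,
        seed=0,
    )
)
relative = standardize_genewise(data.expression).matrix
activity = activity_matrix(relative, data.sets)  # pathways x samples, values in (0, 1)

shifted = next(iter(data.truth.differential))
null_pathway = data.sets.names[-1]
cols = ["normal_000", "normal_001", "tumor_000", "tumor_001"]
print(activity.loc[[shifted, null_pathway], cols].round(3))
print(
    f"\n{shifted} is planted 1.5 sd higher in tumors: its AR-score sits well above 0.5\n"
    "there (members rank near the top). The unshifted pathway fluctuates around the\n"
    "null expectation 0.5 with no tumor/normal trend - its wiggles reflect the\n"
    "pathway's own latent activity varying from sample to sample."
)
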