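"""Generate the synthetic aphid-infestation experiment.

48 libraries (4 genotypes x mock/aphid x 6/12 h x 3 replicates), 4000 genes
with planted effect classes; most effects are planted at 6 h only, so the
early pyramid response is transient by construction.
"""

from common import DESIGN, SIM_CONFIG, SIM_DIR

from ragsynergy import data_io, simdata

SIM_DIR.mkdir(parents=True, exist_ok=True)

truth, matrix = simdata.simulate(SIM_CONFIG, DESIGN)
data_io.write_counts(matrix, SIM_DIR / "counts.tsv", SIM_DIR / "samples.csv")
truth.write(SIM_DIR / "truth.tsv")

print(f"simulated {matrix.n_genes} genes x {matrix.n_samples} samples")
print("planted class counts:")
print(truth.classes.value_counts().to_string())
print(f"wrote counts, sample sheet and truth to {SIM_DIR}")
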