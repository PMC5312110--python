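import numpy as np
import pandas as pd
import pytest

from dosereg.io_formats import ExpressionMatrix, SampleDesign, SampleRecord


def make_matrix(values, probe_ids=None, sample_ids=None, detection_p=None,
                gene_symbols=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a plain 2-D array."""
    values = np.asarray(values, float)
    n, m = values.shape
    probes = probe_ids or [f"P{i + 1:03d}" for i in range(n)]
    samples = sample_ids or [f"S{j + 1}" for j in range(m)]
    det = detection_p if detection_p is not None else np.full((n, m), 0.99)
    return ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=samples),
        pd.DataFrame(np.asarray(det, float), index=probes, columns=samples),
        gene_symbols or {p: p for p in probes},
    )


def ladder_design(reps: int = 3) -> SampleDesign:
    genos = [("WT", 2, 2), ("Pax1KO", 0, 2), ("Pax1KO_Pax9Het", 0, 1),
             ("Pax1KO_Pax9KO", 0, 0)]
    recs = [SampleRecord(f"{g}_rep{r + 1}", g, p1, p9, r + 1)
            for g, p1, p9 in genos for r in range(reps)]
    return SampleDesign(recs)


def ladder_matrix_from_log2(log2_means, reps: int = 3, noise_sd: float = 0.0,
                            rng=None) -> ExpressionMatrix:
    """Matrix whose per-genotype means follow the given n_genes x 4 log2 table."""
    log2_means = np.atleast_2d(np.asarray(log2_means, float))
    n = log2_means.shape[0]
    rng = rng or np.random.default_rng(0)
    noise = rng.normal(0, noise_sd, (n, 4, reps)) if noise_sd else np.zeros((n, 4, reps))
    vals = 2.0 ** (log2_means[:, :, None] + noise)
    design = ladder_design(reps)
    samples = [r.sample_id for r in design.records]
    return make_matrix(vals.reshape(n, 4 * reps),
                       probe_ids=[f"G{i + 1:03d}" for i in range(n)],
                       sample_ids=samples)


@pytest.fixture(scope="session")
def design3() -> SampleDesign:
    return ladder_design(3)
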