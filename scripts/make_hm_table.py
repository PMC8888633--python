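"""Regenerate the AUC-correlation lookup table shipped with the package.

The table gives r = corr(A_hat_1, A_hat_2), the correlation between two
empirical AUC estimates computed on the same cases, as a function of the
average between-modality Pearson correlation of the underlying scores
(r_avg, rows) and the average AUC (A, columns).  Entries are derived
from the binormal model: scores of the two modalities are bivariate
normal with correlation r_avg within each class, each modality
discriminating at AUC A.  In the large-sample limit the correlation of
the two Mann-Whitney AUC estimators reduces to

    r = (L(r_avg / 2) - A^2) / (L(1/2) - A^2),

where L(c) = P(Z1 <= a, Z2 <= a) for standard bivariate normal (Z1, Z2)
with correlation c and a = Phi^{-1}(A): the c = r_avg/2 term is the
concordance of pair indicators sharing one case across modalities, and
the c = 1/2 term the within-modality analogue.  Boundaries check out:
r_avg = 0 gives r = 0 (L(0) = A^2) and r_avg = 1 gives r = 1.

The shipped file is synthetic in the sense that it is computed from
this model rather than transcribed from a published table.

Usage:  python scripts/make_hm_table.py
"""

from pathlib import Path

import numpy as np
from scipy.stats import multivariate_normal, norm

OUT = Path(__file__).resolve().parent.parent / "src" / "cdis" / "data" / (
    "hanley_mcneil_r_table_synthetic.tsv"
)

R_GRID = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.02), 2)
A_GRID = np.round(np.concatenate([np.arange(0.50, 0.99 + 1e-9, 0.01), [0.995]]), 3)


def bvn_cdf(a: float, c: float) -> float:
    c = min(max(c, -0.9999), 0.9999)
    return float(multivariate_normal(mean=[0, 0], cov=[[1, c], [c, 1]]).cdf([a, a]))


def main() -> None:
    table = np.empty((len(R_GRID), len(A_GRID)))
    for j, A in enumerate(A_GRID):
        a = norm.ppf(A)
        denom = bvn_cdf(a, 0.5) - A * A
        for i, r_avg in enumerate(R_GRID):
            table[i, j] = (bvn_cdf(a, r_avg / 2.0) - A * A) / denom
    table = np.clip(table, -1.0, 1.0)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        fh.write(
            "# Correlation r between two empirical AUC estimates sharing cases,\n"
            "# as a function of the average between-modality Pearson correlation\n"
            "# (rows) and the average AUC (columns).  Computed from the binormal\n"
            "# large-sample model (see scripts/make_hm_table.py); synthetic in the\n"
            "# sense of being model-derived rather than transcribed.\n"
        )
        fh.write("r_avg\\A\t" + "\t".join(f"{a:.3f}" for a in A_GRID) + "\n")
        for i, r_avg in enumerate(R_GRID):
            fh.write(
                f"{r_avg:.2f}\t"
                + "\t".join(f"{v:.4f}" for v in table[i])
                + "\n"
            )
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
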