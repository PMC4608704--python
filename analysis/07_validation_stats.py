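"""Validation statistics: qPCR quantification, amplification efficiency,
and the expression/ancestrality/loss association test.

Quantifies each Ct record as 2^-dCt x 1e6 (Ct cutoff 32), estimates
per-well amplification efficiencies (acceptable when > 1.8), and runs the
two-sided Fisher's exact test on the published ancestrality-by-polymorphism
marginals (4,927 retrocopies; 1,954 ancestral; 190 polymorphic; 68 both).
"""

from pathlib import Path

import pandas as pd

from retrodup import pipeline as pl
from retrodup.validation_stats import fisher_exact_2x2

D = Path("results") / "inputs"

# ancestrality x polymorphism table from the published marginals
ANCESTRAL_TOTAL = 1954
POLYMORPHIC_TOTAL = 190
BOTH = 68
ALL_RETROCOPIES = 4927


def main() -> None:
    cfg = pl.PipelineConfig(workdir=str(D))
    pl.run(cfg, ["stats"])
    q = pd.read_csv(D / "qpcr_quantities.tsv", sep="\t")
    eff = pd.read_csv(D / "efficiencies.tsv", sep="\t")
    print(q.to_string(index=False))
    print(eff.to_string(index=False))
    a = BOTH
    b = ANCESTRAL_TOTAL - BOTH
    c = POLYMORPHIC_TOTAL - BOTH
    d = ALL_RETROCOPIES - ANCESTRAL_TOTAL - c
    p = fisher_exact_2x2([[a, b], [c, d]])
    print(f"Fisher 2x2 [[{a},{b}],[{c},{d}]]: two-sided p = {p:.4f} "
          f"({'not ' if p > 0.05 else ''}significant at 0.05)")


if __name__ == "__main__":
    main()
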