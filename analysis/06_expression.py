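"""Expression flagging and between-population differential expression.

Flags loci at >= 1 RPM in any sample, then runs the negative-binomial
Wald test (size factors, shrunk MoM dispersion, BH adjustment, mean-count
>= 50 filter) and calls hits at >= 2-fold change with adjusted p < 0.05;
scores calls against the planted fold changes.
"""

from pathlib import Path

import pandas as pd

from retrodup import pipeline as pl

D = Path("results") / "inputs"


def main() -> None:
    cfg = pl.PipelineConfig(workdir=str(D))
    pl.run(cfg, ["express"])
    flags = pd.read_csv(D / "expressed_flags.tsv", sep="\t")
    de = pd.read_csv(D / "differential_expression.tsv", sep="\t")
    truth = pd.read_csv(D / "truth_de.tsv", sep="\t")
    print(f"loci: {len(flags)}; expressed (>=1 RPM in >=1 sample): "
          f"{flags.expressed.sum()}")
    sig = de[de.significant]
    tp = sig.locus.isin(truth.locus).sum()
    print(f"tested: {len(de)}; significant: {len(sig)} "
          f"(true positives {tp}/{len(truth)} planted, "
          f"false positives {len(sig) - tp})")
    print(sig[["locus", "fold_change", "padj"]]
          .sort_values("padj").head(10).to_string(index=False))


if __name__ == "__main__":
    main()
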