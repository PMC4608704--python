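"""Generate the synthetic study inputs.

Writes the full input bundle (genome + gene models, retrocopy-bearing
contigs, deletion VCF + population panel, cross-species alignment blocks +
species tree, per-individual unmapped reads + filter databases, count
matrices, qPCR tables) with machine-readable truth files under
``results/inputs/``.
"""

import sys
from pathlib import Path

from retrodup import pipeline as pl

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20150101


def main() -> None:
    cfg = pl.PipelineConfig(workdir=str(Path("results") / "inputs"),
                            seed=SEED)
    pl.run(cfg, ["simulate"])
    d = Path(cfg.workdir)
    n_files = len(list(d.iterdir()))
    print(f"wrote {n_files} input/truth files to {d} (seed {SEED})")


if __name__ == "__main__":
    main()
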