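"""Generate the ground-truthed synthetic pulldown used by the downstream steps.

Emulates a bait/control AP-MS screen: 2000 unspecific binders shared between
arms, 80 spiked interactors (log2 fold changes 3-8), 6 bait-exclusive
proteins, three replicates per arm with multiplicative noise keeping
within-arm Pearson r above 0.9.

Writes results/sim/quant.tsv and results/sim/truth.tsv.
"""

from pathlib import Path

import pandas as pd

from baitcall import quant_io
from baitcall.synthetic_data import SimConfig, generate_apms_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    cfg = SimConfig(
        n_background=2000, n_interactors=80, n_exclusive=6,
        peptide_count_range=(2, 25), seed=1,
    )
    table, truth = generate_apms_dataset(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    quant_io.write_quant_table(table, OUT / "quant.tsv")
    pd.DataFrame(
        {
            "accession": list(truth.labels),
            "label": list(truth.labels.values()),
            "true_log2_fc": [truth.true_log2_fc[a] for a in truth.labels],
        }
    ).to_csv(OUT / "truth.tsv", sep="\t", index=False)
    counts = pd.Series(truth.labels).value_counts()
    print(f"wrote {table.n_proteins} proteins ({counts.to_dict()}) to {OUT}")


if __name__ == "__main__":
    main()
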