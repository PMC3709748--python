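"""Select differentially expressed miRNAs and genes with SAM + permutation FDR.

Thresholds follow the emulated study: q <= 1e-6 with fold change >= 2.5
for miRNAs and >= 1.9 for genes, both applied two-sidedly. Writes the full
per-feature tables and prints the selection counts.
"""

from pathlib import Path

from mirpin.diffexpr import SamConfig, de_table
from mirpin.io import read_expression_matrix

SEED = 7
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "pipeline"
    out.mkdir(parents=True, exist_ok=True)
    for kind, fc_threshold in (("mirna", 2.5), ("gene", 1.9)):
        matrix, labels = read_expression_matrix(
            ROOT / "study" / f"{kind}_expr.tsv", ROOT / "study" / f"{kind}_labels.tsv")
        config = SamConfig(fc_threshold=fc_threshold, n_permutations=1000, seed=SEED)
        table = de_table(matrix, labels, config)
        table.reset_index(drop=True).to_csv(out / f"de_{kind}.tsv", sep="\t",
                                            index=False, float_format="%.6g")
        n_up = (table["direction"] == "up").sum()
        n_down = (table["direction"] == "down").sum()
        print(f"{kind}: {len(table)} features -> {n_down} down, {n_up} up "
              f"(q<=1e-6, fc>={fc_threshold})")


if __name__ == "__main__":
    main()
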