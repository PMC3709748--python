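"""Evaluate the selected miRNAs as tumor-vs-normal markers on the independent
expression matrix (never used for network construction), reporting AUC,
Hanley-McNeil SE and the one-sided p-value against chance."""

from pathlib import Path

import pandas as pd

from mirpin.io import read_expression_matrix
from mirpin.roc import roc_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "pipeline"
    de = pd.read_csv(out / "de_mirna.tsv", sep="\t")
    selected = sorted(de.loc[de["direction"] != "ns", "feature_id"])
    matrix, labels = read_expression_matrix(
        ROOT / "study" / "roc_expr.tsv", ROOT / "study" / "roc_labels.tsv")
    table = roc_table(matrix, labels, selected, se_mode="observed")
    table.to_csv(out / "roc.tsv", sep="\t", index=False, float_format="%.6g")
    n_sig = (table["p"] < 0.05).sum()
    print(f"{len(table)} markers evaluated on {table['n_pos'].iloc[0]} tumor vs "
          f"{table['n_neg'].iloc[0]} normal samples; {n_sig} significant at p<0.05")
    print(table.sort_values("auc", ascending=False).to_string(index=False))


if __name__ == "__main__":
    main()
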