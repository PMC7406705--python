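"""Characterize the cohort by amyloid status.

Per-feature group summaries (mean/SD for continuous and ordinal factors,
count/% for binary ones) with two-sided tie-corrected Wilcoxon rank-sum
p-values, in the layout of a population-characteristics table.
"""

from pathlib import Path

from dsiscreen import characterize_cohort, read_cohort_csv
from dsiscreen.reports import characteristics_text

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort_csv(OUT / "cohort.csv")
    summary = characterize_cohort(table)
    summary.to_csv(OUT / "table1_characteristics.csv")
    text = characteristics_text(summary, table.n_negative, table.n_positive)
    (OUT / "table1_characteristics.txt").write_text(text)
    print(text)
    sig = summary[summary["p_value"] < 0.05].index.tolist()
    print(f"features separating the groups at p < 0.05: {sig}")


if __name__ == "__main__":
    main()
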