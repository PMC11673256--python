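"""Detection-rate and odds-ratio tables for the working cohort.

Writes the top-20 sex-association tables and the top-5 tables stratified
by decade age bin, sex, and admission year, for both term categories.
"""

from pathlib import Path

from cadnet.records import Category, load_cohort
from cadnet.stats import sex_association_table, stratified_top_k

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    cohort = load_cohort(OUT / "cohort.jsonl")
    for cat in (Category.DIAGNOSIS, Category.COMORBIDITY):
        top = sex_association_table(cohort, cat, top_k=20)
        top.to_csv(OUT / f"table_top_{cat.value}.csv", index=False)
        lead = top.iloc[0]
        print(f"top {cat.value}: {lead['term']} "
              f"({lead['count']} records, {lead['rate_pct']:.2f}%, "
              f"OR {lead['or_rendered']})")
        for strat in ("age_bin", "sex", "admission_year"):
            table = stratified_top_k(cohort, strat, cat, k=5)
            table.to_frame().to_csv(
                OUT / f"table_top5_{cat.value}_by_{strat}.csv", index=False
            )
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
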