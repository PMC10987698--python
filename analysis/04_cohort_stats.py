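#!/usr/bin/env python
"""Cohort statistics: percent changes and repeated-measures ANOVA.

Assembles the long parameter table (concentration at the lowest b-value,
intra-stick diffusivity, ADC, kurtosis; one value per animal, timepoint
and metabolite) from results/quant.csv and results/fits.json, then runs a
repeated-measures two-way ANOVA (disease × metabolite, subject-blocked)
per parameter with Bonferroni-corrected per-metabolite post-hoc
comparisons (n = number of retained metabolites). Writes
results/stats.json.
"""

from pathlib import Path

from dwmrs import io as dio
from dwmrs.pipeline import cohort_table_from_artifacts, stats_to_dict
from dwmrs.stats import rm_anova

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    quant = dio.read_csv(RESULTS / "quant.csv", "quant")
    fits_doc = dio.read_json(RESULTS / "fits.json", "fits")
    table = cohort_table_from_artifacts(quant, fits_doc)
    n_cmp = table["metabolite"].nunique()

    reports = {}
    for parameter in ("conc", "d_intra", "adc", "kurtosis"):
        rep = rm_anova(table, parameter, n_comparisons=n_cmp)
        reports[parameter] = rep
        dis = rep.anova["disease"]
        print(f"\n== {parameter} ==  disease effect: "
              f"F({dis.df},{rep.anova['disease'].df * (len(table.animal.unique()) - 1)})"
              f" = {dis.f:.2f}, p = {dis.p:.4g}")
        for line in rep.posthoc:
            star = "*" if line.p_adj < 0.05 else " "
            print(f"  {line.metabolite:>5s}: {line.pct_change_mean:+7.1f} "
                  f"± {line.pct_change_sd:5.1f} %   p_adj = {line.p_adj:.4f} {star}")

    dio.write_json(stats_to_dict(reports), RESULTS / "stats.json", "stats")
    print(f"\nwrote {RESULTS / 'stats.json'}")


if __name__ == "__main__":
    main()
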