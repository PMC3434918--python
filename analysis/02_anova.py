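#!/usr/bin/env python
"""Three-way ANOVA of both fitness components, plus home/away contrasts.

Reads results/simulated_data.csv (run 01_simulate.py first), fits the
M x R x ST fixed-effects ANOVA for nodule count and ln fruit count — with
and without the uninoculated controls — and runs the post-hoc home-mix
contrasts for the thyme-site vs naive-site genotype groups.  Tables go to
results/anova_*.csv.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from rhizocorr.anova import anova_three_way, contrast_home_away
from rhizocorr.io import read_table

ROOT = pathlib.Path(__file__).resolve().parents[1]
HOME = ["NA1021", "NA216", "NA632"]
NAIVE = ["A17", "DZA012", "F20089-B"]


def main():
    df = read_table(ROOT / "results" / "simulated_data.csv")
    for response in ("nodules", "ln_fruit"):
        for include_control in (False, True):
            table = anova_three_way(df, response, include_control=include_control)
            tag = f"{response}{'_with_control' if include_control else ''}"
            table.to_frame().to_csv(ROOT / "results" / f"anova_{tag}.csv", index=False)
            print(f"\n=== {tag} (R^2 = {table.r_squared:.2f}) ===")
            for row in table.rows:
                f = "" if row.f is None else f"F={row.f:7.2f} p={row.p:.3g}"
                print(f"  {row.source:<10s} df={row.df:<3d} SS={row.ss:12.2f}  {f}")

    print("\n=== home-mix contrasts on nodule count ===")
    for label, genos in (("thyme-site genotypes", HOME), ("naive genotypes", NAIVE)):
        res = contrast_home_away(df, genos, "rhizobium_mix", "nodules")
        print(f"  {label}: t = {res.t:.2f}, df = {res.df:.0f}, p = {res.p:.3f}  "
              f"(means: {res.group_means[0][1]:.1f} vs {res.group_means[1][1]:.1f})")


if __name__ == "__main__":
    main()
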