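"""Life expectancy at age 30 under population, CS and IP weighting.

Runs the census-schema pipeline — participation model with survival
information on the full population, IP weights for participants, weighted
censored skew-normal fits with delayed entry per gender — and compares
remaining life expectancy at age 30 across schemes.

By default the analysis runs on the packaged synthetic census generator
(the anonymized real linkage is an external download; place it at
data/SwissCensus2010.csv to analyse it instead).  On the synthetic data the
qualitative result mirrors the real one: CS weighting overestimates LE
because the dead are under-represented among participants; IP weighting
recovers the population value.

Writes results/life_expectancy.csv.
"""

import argparse
from pathlib import Path

from ipwmort.census import make_synthetic_census, read_census_csv
from ipwmort.realdata import life_expectancy_by_scheme

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
REAL_DATA = ROOT / "data" / "SwissCensus2010.csv"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n", type=int, default=60_000,
                        help="synthetic census size (ignored with real data)")
    parser.add_argument("--seed", type=int, default=12)
    parser.add_argument("--age", type=float, default=30.0)
    args = parser.parse_args()

    if REAL_DATA.exists():
        print(f"using real anonymized census at {REAL_DATA}")
        census, report = read_census_csv(REAL_DATA)
        print(f"loaded {report['n_rows']} rows, {len(report['errors'])} validation errors")
        min_deaths = 50
    else:
        print(f"real dataset not present; using synthetic census (n={args.n}, seed={args.seed})")
        census = make_synthetic_census(args.n, seed=args.seed)
        min_deaths = 40

    out = life_expectancy_by_scheme(census, at_age=args.age, min_deaths=min_deaths)
    OUT.mkdir(exist_ok=True)
    out.to_csv(OUT / "life_expectancy.csv", index=False)
    print(f"\nRemaining life expectancy at age {args.age:g}:")
    print(out.to_string(index=False))
    for gender in ("Men", "Women"):
        g = out[out.gender == gender].set_index("scheme")["life_expectancy"]
        print(
            f"{gender}: population {g['statpop']:.1f} y, "
            f"CS-weighted {g['se_cs']:.1f} y "
            f"(bias {g['se_cs'] - g['statpop']:+.1f}), "
            f"IP-weighted {g['se_ip']:.1f} y "
            f"(bias {g['se_ip'] - g['statpop']:+.1f})"
        )


if __name__ == "__main__":
    main()
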