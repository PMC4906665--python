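"""Per-period network-level parameters and explanatory covariates.

Reads the simulated series from results/data/ and writes the metrics
table (size, connectance, NODF, H2', ISA, niche overlap), the covariate
table (migrant proportion, fruit richness, fruit abundance) and the
per-species core/periphery classification.
"""

from pathlib import Path

import pandas as pd

from tempoweb import TraitTable, core_periphery, covariate_table, metrics_table, read_series
from tempoweb.covariates import read_fai

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data"
    out = ROOT / "results"
    traits = TraitTable.from_csv(data / "traits.csv")
    series = read_series(data / "series.csv", traits=traits)
    fai = read_fai(data / "fai.csv")

    mt = metrics_table(series)
    mt.to_csv(out / "metrics.csv", index=False)
    cov = covariate_table(series, fai)
    cov.to_csv(out / "covariates.csv", index=False)
    cp = pd.concat([core_periphery(m).to_frame() for m in series])
    cp.to_csv(out / "core_periphery.csv", index=False)

    print("network-level parameters per period:")
    print(mt.round(3).to_string(index=False))
    print("\ncovariates per period:")
    print(cov.round(3).to_string(index=False))
    n_core = cp[cp["class"] == "core"].groupby("period").size()
    print(f"\ncore sizes per period: {dict(n_core)}")


if __name__ == "__main__":
    main()
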