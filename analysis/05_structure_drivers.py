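"""Drivers of temporal network structure.

Quasi-Poisson GLMs relate each network-level parameter to (1) migrant
proportion x fruit richness and (2) fruit abundance, after checking the
rank correlation between migrant proportion and fruit abundance.
"""

from pathlib import Path

import pandas as pd

from tempoweb import model_report, spearman

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cov = pd.read_csv(ROOT / "results" / "covariates.csv")
    mt = pd.read_csv(ROOT / "results" / "metrics.csv")

    rs = spearman(cov["prop_migratory"], cov["fruit_abundance"])
    print(f"Spearman r (migrant proportion vs fruit abundance): {rs:.2f}")

    rep = model_report(cov, mt)
    rep.to_csv(ROOT / "results" / "glm_report.csv", index=False)
    sig = rep[(rep["p"] <= 0.05) & (rep["term"] != "intercept")]
    print("\nsignificant driver terms (P <= 0.05):")
    if sig.empty:
        print("  none")
    else:
        print(sig.round(4).to_string(index=False))
    failed = rep[rep["term"].str.startswith("<failed")]
    if not failed.empty:
        pairs = failed[["response", "model"]].drop_duplicates().itertuples(index=False)
        print("\nmodels not fittable (e.g. negative-valued response under a log link):")
        for r, m in pairs:
            print(f"  {r} ~ {m}")


if __name__ == "__main__":
    main()
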