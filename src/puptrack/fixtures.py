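"""Shipped study-table fixtures.

Two small tables from the grey seal pup deployment are bundled with the
package: the per-animal deployment summary (23 animals with functioning
tags; sex coded male = 1, female = 2; one animal missing weaning mass and
post-weaning duration) and the printed model-ranking tables (df, LL, AICc
and the analysis sample size n) for the four trip-characteristic analyses
and the move-persistence model family.  The ranking tables let the AICc
and likelihood-ratio arithmetic be recomputed from published log-
likelihoods without access to the raw telemetry, which was not deposited.

Note: the haulout-duration analysis does not publish its n; the value
stored here (66) is the unique integer consistent with every printed
(df, LL, AICc) row of that table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("puptrack.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def deployment_summary() -> pd.DataFrame:
    """Per-animal deployment table: biometrics, tracking effort, trip counts."""
    return _read("table1_deployments.csv")


def published_rankings(analysis: str | None = None) -> pd.DataFrame:
    """Printed model-ranking rows (analysis, model, df, LL, AICc, n)."""
    df = _read("model_rankings.csv")
    if analysis is not None:
        df = df[df["analysis"] == analysis].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"unknown analysis {analysis!r}")
    return df
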