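"""AICc ranking and likelihood-ratio utilities shared by all model families."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion.

    AICc = -2 LL + 2k + 2k(k+1)/(n - k - 1).  Requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_table(rows: list[dict]) -> pd.DataFrame:
    """Rank models by AICc and attach delta-AICc and Akaike weights.

    Each row needs keys: model, df, LL, n (AICc computed here if absent).
    """
    df = pd.DataFrame(rows).copy()
    if "AICc" not in df:
        df["AICc"] = [aicc(r.LL, int(r.df), int(r.n)) for r in df.itertuples()]
    df = df.sort_values("AICc", kind="mergesort").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-df["dAICc"] / 2.0)
    df["weight"] = rel / rel.sum()
    return df


def lr_test(ll_big: float, ll_small: float, df_big: int, df_small: int) -> dict:
    """Likelihood-ratio test for nested ML fits.

    X2 = 2 (LL_big - LL_small), df = df_big - df_small.
    """
    if df_big <= df_small:
        raise ValueError("LR test requires the larger model to have more df")
    x2 = 2.0 * (ll_big - ll_small)
    dof = df_big - df_small
    return {"chi2": x2, "df": dof, "p": float(stats.chi2.sf(max(x2, 0.0), dof))}
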