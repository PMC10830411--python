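"""Project annual-herb proportions under altered climate.

Applies a fitted quarterly model's coefficients to a future per-region
climate table (same transforms, e.g. log(precipitation+1)) and compares
the result with the model's prediction under current climate. The headline
summary is the fraction of regions whose raw predicted proportion
increases. This is deliberately a first-order exercise: no time lag, no
adaptation, and variability/footprint terms are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import ModelFit, term_columns


def project(fit: ModelFit, current: pd.DataFrame, future: pd.DataFrame) -> pd.DataFrame:
    """Per-region current and future predictions from one fitted model.

    ``current`` and ``future`` are indexed by region and must carry the
    fitted predictors' columns; regions missing from either table or with
    missing climate are omitted. Raw linear predictions may leave [0, 1];
    both raw and clipped values are reported, and ``delta`` (future minus
    current) is computed on the raw scale so the increase/decrease verdict
    is unaffected by clipping.
    """
    cols = sorted(set().union(*(term_columns(t) for t in fit.spec.predictors)))
    common = current.index.intersection(future.index)
    cur = current.loc[common].dropna(subset=[c for c in cols if c in current.columns])
    fut = future.loc[common].dropna(subset=[c for c in cols if c in future.columns])
    regions = cur.index.intersection(fut.index)

    p_cur = fit.predict(current.loc[regions])
    p_fut = fit.predict(future.loc[regions])
    out = pd.DataFrame(
        {
            "p_current": p_cur,
            "p_future": p_fut,
            "p_current_clipped": np.clip(p_cur, 0.0, 1.0),
            "p_future_clipped": np.clip(p_fut, 0.0, 1.0),
            "delta": p_fut - p_cur,
        },
        index=regions,
    )
    out["clipped"] = (out["p_current"] != out["p_current_clipped"]) | (
        out["p_future"] != out["p_future_clipped"]
    )
    out.index.name = "region"
    return out


def increase_fraction(projection: pd.DataFrame) -> float:
    """Fraction of projected regions with a raw-scale proportion increase."""
    if len(projection) == 0:
        return np.nan
    return float((projection["delta"] > 0).mean())
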