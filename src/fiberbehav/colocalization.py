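"""Synaptic-puncta colocalization from per-cell count tables.

A cell counts as SYP+ (putatively innervated: synaptophysin-labeled
presynaptic puncta near its nucleus) or vGLUT2+ (glutamatergic) when
it carries at least 4 puncta of the respective channel.  The two
conditional colocalization fractions — the proportion of SYP+ cells
that are vGLUT2+ and of vGLUT2+ cells that are SYP+ — summarize how
the labeled afferents distribute over cell types.  A validation
helper compares automated against manual nucleus counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fiberbehav.errors import EmptyInputError, ParameterError

__all__ = [
    "Undefined",
    "classify_cells",
    "colocalization_fractions",
    "count_validation",
]


@dataclass(frozen=True)
class Undefined:
    """Sentinel for a fraction whose denominator is empty."""

    reason: str

    def __bool__(self) -> bool:  # undefined is falsy, never a number
        return False

    def __repr__(self) -> str:
        return f"Undefined({self.reason!r})"


def classify_cells(records: pd.DataFrame, threshold: int = 4,
                   vglut2_threshold: int | None = None) -> pd.DataFrame:
    """Add per-channel positivity flags (count >= threshold).

    Channel thresholds are independent; ``vglut2_threshold`` defaults
    to the SYP threshold.
    """
    if threshold < 0 or (vglut2_threshold is not None and vglut2_threshold < 0):
        raise ParameterError("puncta thresholds must be >= 0")
    for col in ("syp_count", "vglut2_count"):
        if col not in records.columns:
            raise ParameterError(f"puncta table missing column {col!r}")
        vals = records[col].to_numpy()
        if not np.all(np.equal(np.mod(vals, 1), 0)) or (vals < 0).any():
            raise ParameterError(f"{col} must contain non-negative integers")
    out = records.copy()
    vg_thr = threshold if vglut2_threshold is None else vglut2_threshold
    out["is_syp_pos"] = out["syp_count"] >= threshold
    out["is_vglut2_pos"] = out["vglut2_count"] >= vg_thr
    return out


def colocalization_fractions(records: pd.DataFrame
                             ) -> tuple[float | Undefined, float | Undefined]:
    """Conditional colocalization fractions from flagged records.

    Returns (fraction of SYP+ cells that are vGLUT2+, fraction of
    vGLUT2+ cells that are SYP+).  A cell positive in both channels
    belongs to both denominators.  An empty denominator yields an
    ``Undefined`` sentinel rather than a division error.
    """
    for col in ("is_syp_pos", "is_vglut2_pos"):
        if col not in records.columns:
            raise ParameterError(
                "records lack positivity flags; run classify_cells first")
    syp = records["is_syp_pos"].to_numpy(dtype=bool)
    vglut2 = records["is_vglut2_pos"].to_numpy(dtype=bool)
    both = int(np.count_nonzero(syp & vglut2))
    if syp.sum() == 0:
        f_sv: float | Undefined = Undefined("no SYP+ cells")
    else:
        f_sv = both / int(syp.sum())
    if vglut2.sum() == 0:
        f_vs: float | Undefined = Undefined("no vGLUT2+ cells")
    else:
        f_vs = both / int(vglut2.sum())
    return f_sv, f_vs


def count_validation(manual: np.ndarray, automated: np.ndarray) -> dict:
    """Automated-vs-manual nucleus count agreement.

    Per image the overcount is (automated - manual) and the percent
    overcount is 100 * (automated - manual) / manual.  Returns means
    and sample standard deviations of both, plus the mean manual count.
    """
    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if manual.size == 0 or automated.size == 0:
        raise EmptyInputError("count_validation requires at least one image pair")
    if manual.shape != automated.shape:
        raise ParameterError("manual and automated counts must be paired")
    if (manual <= 0).any():
        raise ParameterError("manual counts must be > 0 for percent overcount")
    over = automated - manual
    pct = 100.0 * over / manual
    ddof = 1 if manual.size > 1 else 0
    return {
        "mean_overcount": float(over.mean()),
        "sd_overcount": float(over.std(ddof=ddof)),
        "mean_pct_overcount": float(pct.mean()),
        "sd_pct_overcount": float(pct.std(ddof=ddof)),
        "mean_manual_count": float(manual.mean()),
        "n_images": int(manual.size),
    }
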