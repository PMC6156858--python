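"""Plate-screen normalization, QC, hit calling and dose-response confirmation.

Percent inhibition is anchored per plate: the negative (vehicle) control mean
maps to 0% and the positive (cytotoxic QC) control mean to 100%. Values above
100% are legitimate (a compound can kill more than the QC compound) and are
never clamped. Plate quality is summarized by the screening-window
coefficient Z' = 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|; hits are
compounds whose inhibition strictly exceeds the threshold (70% by default),
and are confirmed by a four-parameter logistic (4PL) dose-response fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synthdata import four_pl

__all__ = [
    "DegeneratePlateError",
    "NoResponseError",
    "DoseResponseFit",
    "percent_inhibition",
    "zfactor",
    "normalize_screen",
    "call_hits",
    "fit_4pl",
    "selectivity_profile",
]


class DegeneratePlateError(ValueError):
    """Plate controls do not separate (equal means) or a role is missing."""


class NoResponseError(ValueError):
    """Dose-response data carry no dose dependence; no finite IC50 exists."""


def percent_inhibition(signal, neg_mean: float, pos_mean: float):
    """Anchor-normalized percent inhibition.

    100 * (neg_mean - signal) / (neg_mean - pos_mean): 0% at the negative
    control mean, 100% at the positive control mean, deliberately unclamped.
    """
    if neg_mean == pos_mean:
        raise DegeneratePlateError("control means are equal; plate is degenerate")
    return 100.0 * (neg_mean - np.asarray(signal, dtype=float)) / (neg_mean - pos_mean)


def zfactor(pos_values, neg_values) -> float:
    """Screening-window coefficient Z' = 1 - 3(sd_p + sd_n)/|mu_p - mu_n|.

    Computed from the control wells of one plate (sample sd, ddof=1); always
    <= 1, can be negative for poorly separated controls.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 control values per role")
    delta = abs(pos.mean() - neg.mean())
    if delta == 0:
        raise DegeneratePlateError("control means are equal; Z-factor undefined")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / delta


def normalize_screen(plates: pd.DataFrame) -> pd.DataFrame:
    """Normalize every compound well against its own plate's controls.

    Parameters
    ----------
    plates
        Long-format table with columns plate_id, well, role
        (compound/neg/pos), compound_id, intensity.

    Returns
    -------
    One row per compound well: compound_id, plate_id, pct_inhibition,
    zfactor (of the source plate).
    """
    if not np.isfinite(plates["intensity"]).all():
        raise ValueError("non-finite intensities in plate table")
    results = []
    for plate_id, group in plates.groupby("plate_id", sort=True):
        roles = group.groupby("role")["intensity"]
        for role in ("neg", "pos"):
            if role not in roles.groups or len(roles.get_group(role)) < 2:
                raise DegeneratePlateError(
                    f"plate {plate_id} lacks >= 2 '{role}' control wells"
                )
        neg = roles.get_group("neg").to_numpy()
        pos = roles.get_group("pos").to_numpy()
        z = zfactor(pos, neg)
        compounds = group[group["role"] == "compound"]
        inhib = percent_inhibition(
            compounds["intensity"].to_numpy(), neg.mean(), pos.mean()
        )
        results.append(
            pd.DataFrame(
                {
                    "compound_id": compounds["compound_id"].to_numpy(),
                    "plate_id": plate_id,
                    "pct_inhibition": inhib,
                    "zfactor": z,
                }
            )
        )
    return pd.concat(results, ignore_index=True)


def call_hits(results: pd.DataFrame, threshold: float = 70.0) -> pd.DataFrame:
    """Compounds with pct_inhibition strictly above the threshold.

    Returned sorted by descending inhibition, with a ``hit`` flag column
    added to ``results`` in place being avoided (input untouched).
    """
    if not 0 < threshold < 130:
        raise ValueError("threshold must lie in (0, 130) percent")
    hits = results[results["pct_inhibition"] > threshold]
    return hits.sort_values("pct_inhibition", ascending=False).reset_index(drop=True)


@dataclass
class DoseResponseFit:
    """4PL fit result: viability = bottom + (top-bottom)/(1+(d/ic50)^hill)."""

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    extrapolated: bool  # IC50 outside [min positive dose, max dose]

    def predict(self, doses):
        return four_pl(doses, self.top, self.bottom, self.ic50, self.hill)


def fit_4pl(doses, viability) -> DoseResponseFit:
    """Unweighted least-squares 4PL fit on the viability scale.

    Multi-start: IC50 initialized on a geometric grid over the positive
    doses, Hill slope over {1, 2, -1, -2}; the best RSS wins. IC50 is fitted
    on the log scale to keep it positive. Requires >= 5 distinct doses
    including 0; a flat series raises :class:`NoResponseError`.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.shape != viability.shape:
        raise ValueError("doses and viability must have the same length")
    if len(np.unique(doses)) < 5:
        raise ValueError("need >= 5 distinct doses")
    if 0.0 not in doses:
        raise ValueError("dose series must include 0")
    if np.allclose(viability, viability[0]):
        raise NoResponseError("constant viability at all doses; no finite IC50")

    pos_doses = np.sort(np.unique(doses[doses > 0]))

    def residuals(theta):
        top, bottom, log_ic50, hill = theta
        return four_pl(doses, top, bottom, np.exp(log_ic50), hill) - viability

    top0 = float(viability[doses == doses.min()].mean())
    bottom0 = float(viability[doses == doses.max()].mean())
    ic50_grid = np.geomspace(pos_doses[0], pos_doses[-1], 5)
    best = None
    for ic50_init in ic50_grid:
        for hill_init in (1.0, 2.0, -1.0, -2.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = least_squares(
                    residuals,
                    x0=[top0, bottom0, np.log(ic50_init), hill_init],
                    method="lm",
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                    max_nfev=5000,
                )
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol)
    rss, sol = best
    top, bottom, log_ic50, hill = sol.x
    ic50 = float(np.exp(log_ic50))
    if hill < 0:
        # (d/ic50)^-h parameterizes the same curve with top/bottom swapped
        top, bottom, hill = bottom, top, -hill
    extrapolated = not (pos_doses[0] <= ic50 <= pos_doses[-1])
    if extrapolated:
        warnings.warn(
            f"fitted IC50 {ic50:.3g} uM lies outside the tested dose range "
            f"[{pos_doses[0]:.3g}, {pos_doses[-1]:.3g}]",
            stacklevel=2,
        )
    return DoseResponseFit(
        top=float(top),
        bottom=float(bottom),
        ic50=ic50,
        hill=float(hill),
        rss=rss,
        converged=bool(sol.success),
        extrapolated=extrapolated,
    )


def selectivity_profile(
    fits_by_cell_line: dict[str, DoseResponseFit],
    adapted: str | None = None,
    parental: str | None = None,
    normal: str | None = None,
) -> tuple[pd.DataFrame, bool | None]:
    """Pairwise IC50 ratios across cell lines, plus a selectivity flag.

    Unconverged fits are excluded with a warning. When the three roles are
    named, the flag is True iff IC50(adapted) < IC50(parental) and both are
    below IC50(normal) — a compound preferentially active on acid-adapted
    cells with a safety window over normal epithelium; otherwise None.
    """
    usable = {}
    for line, fit in fits_by_cell_line.items():
        if not fit.converged:
            warnings.warn(f"excluding unconverged fit for cell line {line}", stacklevel=2)
            continue
        usable[line] = fit
    if len(usable) < 2:
        raise ValueError("need converged fits for >= 2 cell lines")
    lines = sorted(usable)
    rows = [
        {
            "numerator": a,
            "denominator": b,
            "ic50_ratio": usable[a].ic50 / usable[b].ic50,
        }
        for a in lines
        for b in lines
        if a != b
    ]
    table = pd.DataFrame(rows).sort_values("ic50_ratio").reset_index(drop=True)
    flag: bool | None = None
    if adapted in usable and parental in usable and normal in usable:
        flag = (
            usable[adapted].ic50 < usable[parental].ic50
            and usable[adapted].ic50 < usable[normal].ic50
            and usable[parental].ic50 < usable[normal].ic50
        )
    return table, flag
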