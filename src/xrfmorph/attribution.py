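"""Discriminant-region scoring and chemical element assignment.

The discriminant model lives in PCA score space, so the landmark-level
question "which energies drive the discrimination?" is answered by chaining
the two contribution layers:

* the contribution of landmark ``l`` to PC ``k`` is the squared loading
  ``L[l,k]^2`` (columns sum to 1);
* the importance ``w_k`` of PC ``k`` to the discrimination is
  ``w_k = sum_j lambda_j * a[k,j]^2``, where ``a[k,j]`` is the LDA scaling
  of PC ``k`` on discriminant axis ``j`` and ``lambda_j`` the axis'
  between-class separation share.

The per-landmark discriminance score is ``s_l = sum_k L[l,k]^2 w_k``,
rescaled to a maximum of 1 ("temperature" profile).  High-scoring energy
regions are then matched against characteristic emission lines to name the
candidate elements behind the discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import LDAModel
from .ordination import PCAResult, landmark_contributions
from .spectra import LANDMARK_GRID
from .xray_lines import emission_lines

DEFAULT_TOLERANCE_KEV = 0.06  # ~half the SDD resolution (>120 eV FWHM at Mn Ka1)


@dataclass(frozen=True)
class DiscriminanceProfile:
    grid: np.ndarray
    score: np.ndarray  # in [0, 1], max exactly 1

    def __post_init__(self) -> None:
        s = np.asarray(self.score, dtype=float)
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("discriminance scores must be finite and non-negative")
        if abs(s.max() - 1.0) > 1e-12:
            raise ValueError("discriminance profile must be normalised to max 1")


def discriminance_profile(pca: PCAResult, lda: LDAModel) -> DiscriminanceProfile:
    """Per-landmark discriminance score from a PCA and an LDA fitted on its scores."""
    k = lda.scalings.shape[0]
    if k > pca.n_components:
        raise ValueError(
            f"LDA uses {k} PCs but the PCA provides only {pca.n_components} components"
        )
    contrib = landmark_contributions(pca, k)          # (p, k)
    w = (lda.scalings**2) @ lda.axis_separation       # (k,)
    score = contrib @ w
    m = score.max()
    if m <= 0:
        raise ValueError("degenerate discriminance profile (no separation)")
    grid = LANDMARK_GRID if pca.center.size == LANDMARK_GRID.size else np.arange(pca.center.size, dtype=float)
    return DiscriminanceProfile(grid=grid.copy(), score=score / m)


def assign_elements(
    energy_kev: float,
    lines: pd.DataFrame | None = None,
    tolerance: float = DEFAULT_TOLERANCE_KEV,
) -> pd.DataFrame:
    """Candidate emission lines within ``tolerance`` of an energy, nearest first."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    table = emission_lines() if lines is None else lines
    delta = (table["energy_kev"] - energy_kev).abs()
    out = table.assign(delta_kev=delta)
    out = out[out["delta_kev"] <= tolerance].sort_values("delta_kev", kind="stable")
    return out.reset_index(drop=True)


def report_discriminant_regions(
    profile: DiscriminanceProfile,
    lines: pd.DataFrame | None = None,
    top_fraction: float = 0.1,
    tolerance: float = DEFAULT_TOLERANCE_KEV,
) -> pd.DataFrame:
    """Contiguous landmark runs above the (1 - top_fraction) score quantile.

    Each run becomes one energy interval, annotated with the candidate
    emission lines at its peak landmark.  Columns: energy_lo, energy_hi,
    peak_energy, peak_score, n_landmarks, elements (list of "El line" strings).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    score = profile.score
    if top_fraction == 1.0:
        hot = np.ones_like(score, dtype=bool)
    else:
        threshold = np.quantile(score, 1.0 - top_fraction)
        hot = score >= threshold
    rows = []
    i = 0
    n = score.size
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hot[j + 1]:
            j += 1
        run = slice(i, j + 1)
        peak = i + int(np.argmax(score[run]))
        cand = assign_elements(profile.grid[peak], lines=lines, tolerance=tolerance)
        rows.append(
            {
                "energy_lo": profile.grid[i],
                "energy_hi": profile.grid[j],
                "peak_energy": profile.grid[peak],
                "peak_score": score[peak],
                "n_landmarks": j - i + 1,
                "elements": [f"{el} {ln}" for el, ln in zip(cand["element"], cand["line"])],
            }
        )
        i = j + 1
    return pd.DataFrame(rows, columns=["energy_lo", "energy_hi", "peak_energy", "peak_score", "n_landmarks", "elements"])


def reported_elements(regions: pd.DataFrame, primary_only: bool = False) -> set[str]:
    """Element symbols named by any discriminant interval's peak candidates.

    With ``primary_only`` an element counts only when its primary line (Ka1,
    or La1 for L-series elements) is among the candidates: Kb1 lines collide
    with other elements' Ka1 (e.g. Cr Kb1 at 5.947 keV under Mn Ka1 at
    5.899 keV), so element presence calls rest on the primary line.
    """
    out: set[str] = set()
    for cands in regions["elements"]:
        for c in cands:
            el, line = c.split()
            if primary_only and line not in ("Ka1", "La1"):
                continue
            out.add(el)
    return out
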