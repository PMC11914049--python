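"""Compositional transforms for benthic cover data.

Percent covers of the seven hard-coral taxa plus the coral-free base
("other benthic") form a closed composition.  This module provides closure,
multiplicative zero replacement (zeros become half the recording resolution,
0.5% -> 0.0025 on the proportion scale), the additive log-ratio transform
against the other-benthic part, its inverse with the normalize-then-floor
rule used for back-transforming fitted curves, and the robust centered
log-ratio used for Aitchison distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey_records import TAXA

#: Denominator part of the alr transform.
OTHER_BENTHIC = "other_benthic"

#: Half the maximum rounding error of recorded cover: 0.5% = 0.0025 proportion.
DEFAULT_DELTA = 0.0025

#: Back-transformed covers below half the rounding error are reported as 0.
FLOOR_PERCENT = 0.25


@dataclass(frozen=True)
class Composition:
    """A closed composition over named parts (proportions summing to 1)."""

    parts: tuple[str, ...]
    values: np.ndarray  # proportions, same order as `parts`

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.parts),):
            raise ValueError("parts and values length mismatch")
        if np.any(values < 0):
            raise ValueError("negative proportion in composition")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {values.sum()!r}, not 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.parts, self.values.tolist()))


@dataclass(frozen=True)
class AlrVector:
    """alr coordinates (log ratios against the denominator part)."""

    coords: dict[str, float]
    denominator: str = OTHER_BENTHIC
    scope: str = "per_taxon"  # or "total_only"

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.coords.values()))):
            raise ValueError("non-finite alr coordinate")


def replace_zeros(comp: Composition, delta: float = DEFAULT_DELTA) -> Composition:
    """Multiplicative zero replacement.

    Each zero part becomes ``delta`` and every nonzero part is rescaled by
    ``1 - k*delta`` (k = number of zeros), so closure and the ratios among
    nonzero parts are preserved.
    """
    values = comp.values
    zero = values == 0.0
    k = int(zero.sum())
    if k == 0:
        return comp
    smallest_nonzero = values[~zero].min() if k < len(values) else np.inf
    if delta >= smallest_nonzero:
        raise ValueError(
            f"delta {delta} is not below the smallest nonzero part "
            f"{smallest_nonzero}; replacement would invert the ordering"
        )
    out = np.where(zero, delta, values * (1.0 - k * delta))
    return Composition(parts=comp.parts, values=out)


def close_composition(
    taxon_percents: dict[str, float],
    total_percent: float | None = None,
    *,
    delta: float = DEFAULT_DELTA,
    tolerance: float = 1e-9,
) -> Composition:
    """Close percent covers into a composition with an other-benthic part.

    In per-taxon scope (``total_percent`` omitted) the other-benthic part is
    ``100 - sum(taxa)``; in total-only scope pass a single ``{"total": ...}``
    mapping or ``total_percent`` alone, and the parts are total vs other.
    Zeros (including a zero denominator) are replaced via
    :func:`replace_zeros` before returning.
    """
    if total_percent is not None and not taxon_percents:
        taxon_percents = {"total": total_percent}
        total_percent = None
    names = list(taxon_percents)
    values = np.array([taxon_percents[n] for n in names], dtype=float)
    if np.any((values < 0) | (values > 100)):
        raise ValueError("percent covers must lie in [0, 100]")
    covered = values.sum()
    if covered > 100.0 + tolerance:
        raise ValueError(f"taxon covers sum to {covered:.6g}% > 100%")
    other = max(100.0 - covered, 0.0)
    comp = Composition(
        parts=tuple(names) + (OTHER_BENTHIC,),
        values=np.append(values, other) / 100.0,
    )
    return replace_zeros(comp, delta=delta)


def alr_transform(comp: Composition, denominator: str = OTHER_BENTHIC) -> AlrVector:
    """Additive log-ratio: ln(part / denominator part) for each named part."""
    values = comp.values
    if np.any(values <= 0):
        raise ValueError(
            "composition has nonpositive parts; apply replace_zeros first"
        )
    if denominator not in comp.parts:
        raise ValueError(f"denominator part {denominator!r} not in composition")
    denom = values[comp.parts.index(denominator)]
    coords = {
        part: float(np.log(v / denom))
        for part, v in zip(comp.parts, values)
        if part != denominator
    }
    scope = "total_only" if list(coords) == ["total"] else "per_taxon"
    return AlrVector(coords=coords, denominator=denominator, scope=scope)


def inverse_alr(
    vec: AlrVector, *, floor_percent: float | None = None
) -> dict[str, float]:
    """Invert an alr vector to percent covers.

    Parts are proportional to ``exp(coord)`` with the denominator part at
    ``exp(0)``; all parts are normalized to sum to 100%.  When
    ``floor_percent`` is given (used for back-transformed fitted curves),
    normalized covers below it are set to 0 *after* normalization, with no
    re-normalization.
    """
    names = list(vec.coords) + [vec.denominator]
    raw = np.exp(np.array(list(vec.coords.values()) + [0.0]))
    percent = 100.0 * raw / raw.sum()
    if floor_percent is not None:
        percent = np.where(percent < floor_percent, 0.0, percent)
    return dict(zip(names, percent.tolist()))


def record_to_alr(
    taxon_percents: dict[str, float],
    total_percent: float | None = None,
    *,
    delta: float = DEFAULT_DELTA,
) -> AlrVector:
    """Convenience: close + zero-replace + alr in one step."""
    return alr_transform(
        close_composition(taxon_percents, total_percent, delta=delta)
    )


def rclr_transform(cover_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Robust centered log-ratio of a samples x parts cover matrix.

    Zero replacement is assumed already applied, so every entry is strictly
    positive; each row is log-transformed and centered by its own mean log.
    Rows therefore sum to zero and are invariant to row scaling.
    """
    x = np.asarray(cover_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D samples x parts matrix")
    if np.any(x < 0):
        raise ValueError("cover matrix must be nonnegative")
    if np.any(x.sum(axis=1) == 0):
        raise ValueError("row of all zeros; apply zero replacement first")
    if np.any(x == 0):
        raise ValueError("zero entries present; apply zero replacement first")
    logs = np.log(x)
    return logs - logs.mean(axis=1, keepdims=True)


def covers_to_closed_matrix(
    frame: pd.DataFrame, *, delta: float = DEFAULT_DELTA
) -> pd.DataFrame:
    """Close a resolved cover table (percent per taxon) row-wise.

    Returns a samples x (taxa + other_benthic) proportion matrix with zero
    replacement applied, ready for :func:`rclr_transform`.
    """
    cols = [t for t in TAXA if t in frame.columns]
    closed = np.empty((len(frame), len(cols) + 1))
    for i, (_, row) in enumerate(frame[cols].iterrows()):
        comp = close_composition({c: float(row[c]) for c in cols}, delta=delta)
        closed[i] = comp.values
    return pd.DataFrame(
        closed, index=frame.index, columns=cols + [OTHER_BENTHIC]
    )
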