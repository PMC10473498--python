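"""Crypt counting: from concave regions to an accepted-bud count.

The counter cuts the smoothed boundary at the midpoints of its concave
"neck" regions. Each boundary segment between two cyclically adjacent neck
midpoints, closed by the chord joining them, is one candidate crypt region.
Two dimensionless descriptors decide acceptance:

    area_norm    = |area of segment + chord|  / total organoid area
    arclen_norm  = segment arc length         / total boundary arc length

A candidate is a crypt iff min_area_norm <= area_norm <= max_area_norm and
arclen_norm >= min_arclen_norm (bounds inclusive). The area window rejects
both noise wiggles (too small) and villus-scale bulk (too large); the
arc-length floor rejects sharp corners that subtend almost no boundary.
Normalisation makes the whole decision scale-free, so one parameter set
serves organoids of any imaged size; parameters are trained per culture day
(:mod:`cryptmorph.training`) because bud geometry changes as organoids grow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boundary_io import BoundaryPolygon, ensure_ccw, signed_area
from .shape_analysis import (
    ConcaveRegion,
    FourierShape,
    circularity,
    curvature_profile,
    default_sample_count,
    find_concave_regions,
    fit_fourier,
    sample_curve,
)

__all__ = [
    "CryptParameters",
    "CandidateRegion",
    "CountResult",
    "candidate_regions",
    "count_crypts",
    "load_parameters",
    "save_parameters",
    "results_to_csv",
]


@dataclass(frozen=True)
class CryptParameters:
    """Per-day crypt-classifier parameters.

    ``harmonics`` may be fractional (optimisers average over runs); it is
    rounded to the nearest integer when applied.
    """

    harmonics: float
    min_area_norm: float
    max_area_norm: float
    min_arclen_norm: float
    day_label: str = ""

    def __post_init__(self) -> None:
        if round(self.harmonics) < 1:
            raise ValueError("harmonics must round to >= 1")
        if not (0.0 < self.min_area_norm < self.max_area_norm <= 1.0):
            raise ValueError(
                "need 0 < min_area_norm < max_area_norm <= 1, got "
                f"({self.min_area_norm}, {self.max_area_norm})"
            )
        if not (0.0 <= self.min_arclen_norm < 1.0):
            raise ValueError("need 0 <= min_arclen_norm < 1")

    @property
    def H(self) -> int:
        """Harmonic count as applied (nearest integer)."""
        return int(round(self.harmonics))


@dataclass(frozen=True)
class CandidateRegion:
    """One boundary segment between adjacent concave midpoints.

    ``seg_start``/``seg_end`` are sample indices on the Fourier curve; the
    segment runs forward (cyclically) from start to end and is closed by
    the chord between the two samples.
    """

    seg_start: int
    seg_end: int
    area_norm: float
    arclen_norm: float
    accepted: bool = False


@dataclass(frozen=True)
class CountResult:
    """Per-organoid counting outcome."""

    organoid_id: str
    crypt_count: int
    candidates: list[CandidateRegion]
    circularity: float
    total_area: float
    total_perimeter: float

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def _segment_indices(start: int, end: int, n: int) -> np.ndarray:
    """Cyclic index range start..end inclusive."""
    if end >= start:
        return np.arange(start, end + 1)
    return np.concatenate([np.arange(start, n), np.arange(0, end + 1)])


def candidate_regions(
    shape: FourierShape,
    concave: list[ConcaveRegion],
    n: int | None = None,
) -> list[CandidateRegion]:
    """Cut the boundary at concave midpoints into candidate crypt segments.

    With fewer than two concave regions no closed sub-region can be
    delimited and the list is empty (a spheroid has no separable bud). The
    k >= 2 midpoints produce exactly k candidates that tile the boundary:
    their ``arclen_norm`` values sum to 1.
    """
    if len(concave) < 2:
        return []
    if n is None:
        n = default_sample_count(shape.H)
    curve = sample_curve(shape, n).points
    seg_len = np.linalg.norm(np.roll(curve, -1, axis=0) - curve, axis=1)
    total_arclen = float(seg_len.sum())
    total_area = abs(signed_area(curve))

    mids = [r.midpoint_index for r in concave]
    out: list[CandidateRegion] = []
    for i, m0 in enumerate(mids):
        m1 = mids[(i + 1) % len(mids)]
        idx = _segment_indices(m0, m1, n)
        seg = curve[idx]
        # shoelace over the open chain implicitly closes it with the chord
        area = abs(signed_area(seg))
        # arc length of the forward path m0 -> m1 (edges between samples)
        arclen = float(seg_len[idx[:-1]].sum())
        out.append(
            CandidateRegion(
                seg_start=int(m0),
                seg_end=int(m1),
                area_norm=float(area / total_area),
                arclen_norm=float(arclen / total_arclen),
            )
        )
    return out


def count_crypts(
    poly: BoundaryPolygon,
    params: CryptParameters,
    organoid_id: str = "",
    kappa_tol: float = 0.0,
    n_samples: int | None = None,
) -> CountResult:
    """Run the full counting pipeline on one boundary.

    Pipeline: canonical ccw orientation -> elliptic-Fourier fit at
    round(params.harmonics) harmonics -> curvature profile -> concave
    regions -> candidate segments -> threshold acceptance. Circularity is
    computed on the sampled Fourier curve (the smoothed outline).
    """
    try:
        poly = ensure_ccw(poly)
        shape = fit_fourier(poly, params.H)
        n = n_samples if n_samples is not None else default_sample_count(shape.H)
        profile = curvature_profile(shape, n)
        concave = find_concave_regions(profile, kappa_tol=kappa_tol)
        cands = candidate_regions(shape, concave, n)
        smooth = sample_curve(shape, n)
    except ValueError as exc:
        raise ValueError(f"organoid {organoid_id or '<unnamed>'}: {exc}") from exc

    accepted: list[CandidateRegion] = []
    for c in cands:
        ok = (
            params.min_area_norm <= c.area_norm <= params.max_area_norm
            and c.arclen_norm >= params.min_arclen_norm
        )
        accepted.append(
            CandidateRegion(c.seg_start, c.seg_end, c.area_norm, c.arclen_norm, ok)
        )
    return CountResult(
        organoid_id=organoid_id,
        crypt_count=sum(c.accepted for c in accepted),
        candidates=accepted,
        circularity=circularity(smooth),
        total_area=smooth.area,
        total_perimeter=smooth.perimeter,
    )


# ---------------------------------------------------------------------------
# parameter-file and result I/O
# ---------------------------------------------------------------------------

_FIELDS = ("harmonics", "min_area_norm", "max_area_norm", "min_arclen_norm")


def save_parameters(params: dict[str, CryptParameters], path: str | Path) -> None:
    """Write a day-keyed parameter file (YAML or JSON by extension)."""
    payload = {
        day: {f: getattr(p, f) for f in _FIELDS} for day, p in params.items()
    }
    path = Path(path)
    text = (
        json.dumps(payload, indent=2)
        if path.suffix.lower() == ".json"
        else yaml.safe_dump(payload, sort_keys=False)
    )
    path.write_text(text)


def load_parameters(path: str | Path) -> dict[str, CryptParameters]:
    """Read a day-keyed parameter file written by :func:`save_parameters`."""
    path = Path(path)
    raw = (
        json.loads(path.read_text())
        if path.suffix.lower() == ".json"
        else yaml.safe_load(path.read_text())
    )
    out: dict[str, CryptParameters] = {}
    for day, vals in raw.items():
        missing = set(_FIELDS) - set(vals)
        if missing:
            raise ValueError(f"parameter entry '{day}' missing {sorted(missing)}")
        out[str(day)] = CryptParameters(day_label=str(day), **{f: float(vals[f]) for f in _FIELDS})
    return out


def results_to_csv(results: list[CountResult], path: str | Path) -> None:
    """Write per-organoid counts: organoid_id, crypt_count, circularity, ..."""
    pd.DataFrame(
        {
            "organoid_id": [r.organoid_id for r in results],
            "crypt_count": [r.crypt_count for r in results],
            "circularity": [r.circularity for r in results],
            "n_candidates": [r.n_candidates for r in results],
            "total_area": [r.total_area for r in results],
            "total_perimeter": [r.total_perimeter for r in results],
        }
    ).to_csv(path, index=False)
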