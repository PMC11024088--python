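"""Entropy-based feature scoring and selection.

The discrimination score used throughout (``midse``) compares the
class-conditional value distributions of a descriptor on a shared
equidistant binning: it is the Shannon entropy of the per-bin mean of the
two class histograms minus the mean of the per-class entropies.  With log
base 2 the score lies in [0, 1]: 0 for identical distributions, 1 when the
two classes occupy disjoint single bins.  Because each class is normalised
to a probability vector before comparison, the score does not depend on the
class sizes.

Selection proceeds in two independent streams:

* continuous descriptors — scored, thresholded, ordered by score, then a
  greedy Pearson-correlation redundancy filter, then a hard cap;
* structural keys — 2D descriptors whose missing value signals the absence
  of a substructure, retained when the per-class absence frequencies differ
  by at least ``diff_cut``.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import InputError, ScoringError

logger = logging.getLogger(__name__)

__all__ = [
    "ClassHistogramPair",
    "FeatureScore",
    "StructuralKey",
    "FeatureSelection",
    "shannon_entropy",
    "bin_feature",
    "midse",
    "select_structural_keys",
    "select_continuous_features",
]


@dataclass(frozen=True)
class ClassHistogramPair:
    """Per-class and combined bin probabilities on shared equidistant edges.

    The combined histogram is the per-bin arithmetic mean of the two class
    histograms (NOT the pooled histogram), which is what makes the derived
    score class-size invariant.
    """

    bin_edges: Tuple[float, ...]
    p_active: Tuple[float, ...]
    p_inactive: Tuple[float, ...]
    p_combined: Tuple[float, ...]


@dataclass(frozen=True)
class FeatureScore:
    descriptor_name: str
    midse: float
    h_active: float
    h_inactive: float
    h_combined: float
    histograms: ClassHistogramPair

    def to_dict(self) -> dict:
        return {
            "descriptor_name": self.descriptor_name,
            "midse": self.midse,
            "h_active": self.h_active,
            "h_inactive": self.h_inactive,
            "h_combined": self.h_combined,
            "bin_edges": list(self.histograms.bin_edges),
            "p_active": list(self.histograms.p_active),
            "p_inactive": list(self.histograms.p_inactive),
            "p_combined": list(self.histograms.p_combined),
        }


@dataclass(frozen=True)
class StructuralKey:
    """A substructure presence/absence feature derived from missing values."""

    descriptor_name: str
    absence_freq_active: float
    absence_freq_inactive: float

    @property
    def discrepancy(self) -> float:
        return abs(self.absence_freq_active - self.absence_freq_inactive)


@dataclass
class FeatureSelection:
    """Retained continuous descriptors (descending score) plus structural keys."""

    continuous_descriptors: List[FeatureScore]
    structural_keys: List[StructuralKey] = field(default_factory=list)
    set_tag: str = "2D"

    @property
    def descriptor_names(self) -> List[str]:
        return [fs.descriptor_name for fs in self.continuous_descriptors]

    @property
    def structural_key_names(self) -> List[str]:
        return [sk.descriptor_name for sk in self.structural_keys]

    def to_json(self) -> str:
        return json.dumps(
            {
                "set_tag": self.set_tag,
                "continuous_descriptors": [
                    fs.to_dict() for fs in self.continuous_descriptors
                ],
                "structural_keys": [
                    {
                        "descriptor_name": sk.descriptor_name,
                        "absence_freq_active": sk.absence_freq_active,
                        "absence_freq_inactive": sk.absence_freq_inactive,
                    }
                    for sk in self.structural_keys
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSelection":
        d = json.loads(text)
        scores = [
            FeatureScore(
                descriptor_name=e["descriptor_name"],
                midse=e["midse"],
                h_active=e["h_active"],
                h_inactive=e["h_inactive"],
                h_combined=e["h_combined"],
                histograms=ClassHistogramPair(
                    bin_edges=tuple(e["bin_edges"]),
                    p_active=tuple(e["p_active"]),
                    p_inactive=tuple(e["p_inactive"]),
                    p_combined=tuple(e["p_combined"]),
                ),
            )
            for e in d["continuous_descriptors"]
        ]
        keys = [
            StructuralKey(
                descriptor_name=e["descriptor_name"],
                absence_freq_active=e["absence_freq_active"],
                absence_freq_inactive=e["absence_freq_inactive"],
            )
            for e in d["structural_keys"]
        ]
        return cls(continuous_descriptors=scores, structural_keys=keys,
                   set_tag=d.get("set_tag", "2D"))

    def ranked_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "descriptor": self.descriptor_names,
                "midse": [fs.midse for fs in self.continuous_descriptors],
                "h_active": [fs.h_active for fs in self.continuous_descriptors],
                "h_inactive": [fs.h_inactive for fs in self.continuous_descriptors],
                "h_combined": [fs.h_combined for fs in self.continuous_descriptors],
            }
        )


def shannon_entropy(p: Sequence[float]) -> float:
    """Shannon entropy in bits; zero-probability bins contribute nothing."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise InputError("empty probability vector")
    if np.any(arr < 0):
        raise InputError("probability vector has negative entries")
    if not np.isclose(arr.sum(), 1.0, atol=1e-8):
        raise InputError(f"probability vector sums to {arr.sum()}, not 1")
    nz = arr[arr > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    return arr[np.isfinite(arr)]


def bin_feature(
    values_active: Sequence[float],
    values_inactive: Sequence[float],
    n_bins: int,
) -> ClassHistogramPair:
    """Histogram both classes on equidistant bins over the combined range.

    Missing (NaN/inf) values are excluded.  A degenerate combined range
    (all values equal) collapses to a single effective bin.
    """
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    a = _clean(values_active)
    b = _clean(values_inactive)
    if a.size == 0 or b.size == 0:
        raise ScoringError("a class has no non-missing values")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        # zero value range: single effective bin
        edges = np.array([lo, hi])
        pa = pi = np.array([1.0])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        ca, _ = np.histogram(a, bins=edges)
        cb, _ = np.histogram(b, bins=edges)
        pa = ca / ca.sum()
        pi = cb / cb.sum()
    pc = (pa + pi) / 2.0
    return ClassHistogramPair(
        bin_edges=tuple(edges.tolist()),
        p_active=tuple(pa.tolist()),
        p_inactive=tuple(pi.tolist()),
        p_combined=tuple(pc.tolist()),
    )


def midse(
    values_active: Sequence[float],
    values_inactive: Sequence[float],
    n_bins: int = 10,
    descriptor_name: str = "",
) -> FeatureScore:
    """Differential-entropy discrimination score of one descriptor.

    ``H(mean histogram) - (H(active) + H(inactive)) / 2`` with log base 2,
    so the score is in [0, 1].
    """
    hist = bin_feature(values_active, values_inactive, n_bins)
    h_a = shannon_entropy(hist.p_active)
    h_b = shannon_entropy(hist.p_inactive)
    h_ab = shannon_entropy(hist.p_combined)
    score = h_ab - (h_a + h_b) / 2.0
    # numerical guard only; the formula is bounded by [0, 1] analytically
    score = min(max(score, 0.0), 1.0)
    return FeatureScore(
        descriptor_name=descriptor_name,
        midse=score,
        h_active=h_a,
        h_inactive=h_b,
        h_combined=h_ab,
        histograms=hist,
    )


# MIN/MAX electrotopological-state twins (MINtsC / MAXtsC, ...) carry the same
# absence information; only the MAX member is eligible as a structural key.
_MIN_PREFIX = re.compile(r"^MIN")
# Sum-of-E-state descriptors (SsCH3, SdO, SaaN, ...) return 0, not missing,
# when the atom type is absent, so they can never act as structural keys.
_SUM_ESTATE = re.compile(r"^S[sdta]")


def _is_sum_estate(name: str) -> bool:
    return bool(_SUM_ESTATE.match(name))


def select_structural_keys(
    table,
    labels: Sequence[int],
    diff_cut: float = 0.2,
) -> List[StructuralKey]:
    """Retain 2D descriptors whose per-class absence frequencies differ enough.

    ``table`` is a :class:`~bbbkit.data_model.DescriptorTable` (or any object
    with ``frame`` and ``dimension_tag``); only descriptors tagged 2D are
    considered.
    """
    frame: pd.DataFrame = table.frame
    tags = table.dimension_tags
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != frame.shape[0]:
        raise InputError("labels length does not match table rows")
    act = y == 1
    ina = y == 0
    names = list(frame.columns)
    name_set = set(names)
    keys: List[StructuralKey] = []
    for name in names:
        if tags.get(name, "2D") != "2D":
            continue
        if _is_sum_estate(name):
            continue
        if _MIN_PREFIX.match(name) and ("MAX" + name[3:]) in name_set:
            continue  # MIN twin of a MAX descriptor
        col = frame[name].to_numpy(dtype=float)
        fa = float(np.mean(~np.isfinite(col[act]))) if act.any() else 0.0
        fi = float(np.mean(~np.isfinite(col[ina]))) if ina.any() else 0.0
        if abs(fa - fi) >= diff_cut:
            keys.append(
                StructuralKey(
                    descriptor_name=name,
                    absence_freq_active=fa,
                    absence_freq_inactive=fi,
                )
            )
    keys.sort(key=lambda k: (-k.discrepancy, k.descriptor_name))
    return keys


def _pairwise_complete_pcc(x: np.ndarray, y: np.ndarray) -> float:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return 0.0
    xv, yv = x[mask], y[mask]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1])


def select_continuous_features(
    table,
    labels: Sequence[int],
    n_bins: int = 10,
    max_n: int = 50,
    min_score: float = 0.1,
    pcc_cut: float = 0.8,
    min_per_class: int = 5,
    set_tag: Optional[str] = None,
    structural_keys: Optional[List[StructuralKey]] = None,
) -> FeatureSelection:
    """Score every descriptor and apply threshold → greedy PCC filter → cap.

    Candidates are walked from highest score downward (ties broken by
    descriptor name); a candidate is dropped if its |PCC| with any already
    retained descriptor is >= ``pcc_cut``, computed on pairwise-complete
    observations.  At most ``max_n`` descriptors survive.
    """
    frame: pd.DataFrame = table.frame
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != frame.shape[0]:
        raise InputError("labels length does not match table rows")
    act = y == 1
    ina = y == 0

    scores: List[FeatureScore] = []
    for name in frame.columns:
        col = frame[name].to_numpy(dtype=float)
        va = col[act]
        vi = col[ina]
        if (np.isfinite(va).sum() < min_per_class
                or np.isfinite(vi).sum() < min_per_class):
            logger.warning("skipping %s: <%d non-missing values in a class",
                           name, min_per_class)
            continue
        try:
            scores.append(midse(va, vi, n_bins=n_bins, descriptor_name=name))
        except ScoringError as exc:
            logger.warning("skipping %s: %s", name, exc)

    qualified = [s for s in scores if s.midse >= min_score]
    qualified.sort(key=lambda s: (-s.midse, s.descriptor_name))

    retained: List[FeatureScore] = []
    for cand in qualified:
        if len(retained) >= max_n:
            break
        cx = frame[cand.descriptor_name].to_numpy(dtype=float)
        redundant = False
        for kept in retained:
            kx = frame[kept.descriptor_name].to_numpy(dtype=float)
            if abs(_pairwise_complete_pcc(cx, kx)) >= pcc_cut:
                redundant = True
                break
        if not redundant:
            retained.append(cand)

    if not retained:
        warnings.warn("feature selection retained zero descriptors")

    return FeatureSelection(
        continuous_descriptors=retained,
        structural_keys=structural_keys or [],
        set_tag=set_tag or getattr(table, "set_tag", "2D"),
    )
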