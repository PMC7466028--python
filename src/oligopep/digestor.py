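"""In-silico DNase I digestion and LC-MS footprint analysis.

DNase I hydrolyses the phosphodiester backbone leaving 5'-phosphate /
3'-OH products, so every internal fragment end carries those chemistries;
fragment ends that coincide with the parent termini keep the parent
chemistry.  Bond ``p`` (1..n-1) lies between residues ``p`` and ``p+1`` on
the 5'->3' strand.

The analysis chain is: enumerate all contiguous fragments of the parent
strand -> assign observed peaks to (fragment, charge) candidates within a
ppm tolerance -> accumulate assigned peak areas into a per-bond (or
per-length) cleavage profile -> compare bound vs free profiles as log2
ratios -> call a protected window where cleavage is suppressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import MatchingError, ProfileError
from .massbook import (
    ElementalComposition,
    ModifiedOligo,
    Scale,
    mz_for_charges,
)

ProfileMode = Literal["per_bond", "per_length"]


@dataclass(frozen=True)
class Fragment:
    """A contiguous sub-oligo produced by digestion (1-based inclusive)."""

    parent_id: str
    start: int
    end: int
    oligo: ModifiedOligo

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def composition(self) -> ElementalComposition:
        return self.oligo.composition()

    def neutral_mass(self, scale: Scale = "monoisotopic") -> float:
        return self.oligo.composition().mass(scale)

    def __repr__(self) -> str:  # compact span form used in outputs
        return f"Fragment({self.parent_id}:{self.start}-{self.end})"


def fragment_oligo(parent: ModifiedOligo, start: int, end: int) -> Fragment:
    """Build the sub-oligo for span [start, end] with digestion chemistry."""
    n = len(parent)
    if not 1 <= start <= end <= n:
        raise ProfileError(f"span [{start},{end}] outside 1..{n}")
    five = parent.five_prime if start == 1 else "phosphate"
    three = parent.three_prime if end == n else "OH"
    mods = tuple(
        (pos - start + 1, mod_id)
        for pos, mod_id in parent.modifications
        if start <= pos <= end
    )
    sub = ModifiedOligo(
        id=f"{parent.id}[{start}-{end}]",
        sequence=parent.sequence[start - 1 : end],
        five_prime=five,
        three_prime=three,
        modifications=mods,
    )
    return Fragment(parent.id, start, end, sub)


def enumerate_fragments(parent: ModifiedOligo) -> list[Fragment]:
    """All n(n+1)/2 contiguous fragments of the parent strand."""
    n = len(parent)
    return [
        fragment_oligo(parent, s, e)
        for s in range(1, n + 1)
        for e in range(s, n + 1)
    ]


@dataclass
class PeakList:
    """Observed LC-MS peaks: m/z, integrated area, optional retention time."""

    mz: np.ndarray
    area: np.ndarray
    rt: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.mz.shape != self.area.shape:
            raise MatchingError("mz and area must have the same length")
        if np.any(self.mz <= 0):
            raise MatchingError("all m/z values must be positive")
        if np.any(self.area < 0):
            raise MatchingError("peak areas must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)

    def to_frame(self) -> pd.DataFrame:
        d = {"mz": self.mz, "area": self.area}
        if self.rt is not None:
            d["rt"] = self.rt
        return pd.DataFrame(d)


@dataclass(frozen=True)
class Candidate:
    """One (fragment, charge) explanation of a peak."""

    fragment: Fragment
    z: int
    ppm_error: float


@dataclass
class Assignment:
    """All retained candidates for one peak.

    Composition-isobaric candidates (identical elemental composition, hence
    identical predicted m/z at every charge) are collapsed into ambiguity
    groups; ``group_ids`` parallels ``candidates``.
    """

    peak_index: int
    mz: float
    area: float
    candidates: list[Candidate] = field(default_factory=list)
    group_ids: list[int] = field(default_factory=list)

    @property
    def assigned(self) -> bool:
        return bool(self.candidates)


def match_peaks(
    peaks: PeakList,
    fragments: Sequence[Fragment],
    tol_ppm: float = 25.0,
    charges: Sequence[int] = (1, 2, 3, 4, 5, 6),
    scale: Scale = "monoisotopic",
) -> list[Assignment]:
    """Assign each peak to every (fragment, z) within the ppm tolerance.

    ppm error is signed, ``(observed - predicted) / predicted * 1e6``.
    Peaks with no candidate are returned with an empty candidate list.
    """
    if tol_ppm <= 0:
        raise MatchingError(f"tol_ppm must be positive, got {tol_ppm}")
    if not fragments:
        raise MatchingError("cannot match against an empty fragment list")

    # Precompute predicted m/z for every (fragment, z); group ids key on
    # elemental composition so isobars share a group.
    comp_key: dict[str, int] = {}
    pred_mz, pred_frag, pred_z, pred_group = [], [], [], []
    for frag in fragments:
        formula = frag.composition().formula()
        gid = comp_key.setdefault(formula, len(comp_key))
        for z, mz in mz_for_charges(frag.neutral_mass(scale), charges, scale=scale):
            pred_mz.append(mz)
            pred_frag.append(frag)
            pred_z.append(z)
            pred_group.append(gid)
    order = np.argsort(pred_mz)
    pred_mz_arr = np.asarray(pred_mz)[order]
    pred_idx = np.asarray(range(len(pred_mz)))[order]

    out: list[Assignment] = []
    for i, (mz_obs, area) in enumerate(zip(peaks.mz, peaks.area)):
        tol_da = mz_obs * tol_ppm * 1e-6
        lo = np.searchsorted(pred_mz_arr, mz_obs - tol_da, side="left")
        hi = np.searchsorted(pred_mz_arr, mz_obs + tol_da, side="right")
        a = Assignment(peak_index=i, mz=float(mz_obs), area=float(area))
        for j in pred_idx[lo:hi]:
            ppm = (mz_obs - pred_mz[j]) / pred_mz[j] * 1e6
            if abs(ppm) <= tol_ppm:
                a.candidates.append(Candidate(pred_frag[j], pred_z[j], float(ppm)))
                a.group_ids.append(pred_group[j])
        out.append(a)
    return out


@dataclass
class CleavageProfile:
    """Normalized cleavage intensity over bonds (or fragment lengths)."""

    parent_id: str
    mode: ProfileMode
    values: np.ndarray  # per_bond: index 0 is bond 1; per_length: length 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        col = "bond" if self.mode == "per_bond" else "length"
        return pd.DataFrame(
            {col: np.arange(1, self.n_bins + 1), "value": self.values}
        )


def build_profile(
    assignments: Sequence[Assignment],
    parent: ModifiedOligo,
    mode: ProfileMode = "per_bond",
) -> CleavageProfile:
    """Accumulate assigned peak areas into a normalized cleavage profile.

    ``per_bond``: each *internal* fragment end deposits the peak's area on
    the bond whose cleavage produced it (5' end of fragment (s,e) with s>1
    comes from bond s-1; 3' end with e<n from bond e).  ``per_length``: area
    is summed by fragment length, the proxy for the gel-like fragment-size
    axis.  A peak's area is split equally across all its distinct candidate
    fragments (the ambiguity rule).
    """
    if not assignments:
        raise ProfileError("no assignments supplied")
    n = len(parent)
    size = n - 1 if mode == "per_bond" else n
    acc = np.zeros(size)
    any_assigned = False
    for a in assignments:
        frags = {(c.fragment.start, c.fragment.end): c.fragment for c in a.candidates}
        if not frags:
            continue
        any_assigned = True
        share = a.area / len(frags)
        for (s, e), frag in frags.items():
            if mode == "per_length":
                acc[frag.length - 1] += share
            else:
                if s > 1:
                    acc[s - 2] += share
                if e < n:
                    acc[e - 1] += share
    if not any_assigned:
        raise ProfileError("all peaks unassigned; profile undefined")
    total = acc.sum()
    if total <= 0:
        raise ProfileError("assigned area is zero; profile undefined")
    return CleavageProfile(parent.id, mode, acc / total)


def protection_score(
    free: CleavageProfile,
    bound: CleavageProfile,
    pseudocount: float | None = None,
) -> np.ndarray:
    """Per-bond log2(bound/free) with a pseudocount; negative = protected.

    The default pseudocount is ``1 / (10 * n_bins)`` — a tenth of the
    uniform-profile bin value.
    """
    if free.parent_id != bound.parent_id or free.n_bins != bound.n_bins:
        raise ProfileError(
            f"profiles disagree: {free.parent_id}/{free.n_bins} vs "
            f"{bound.parent_id}/{bound.n_bins}"
        )
    if free.mode != bound.mode:
        raise ProfileError("profiles must use the same mode")
    if pseudocount is None:
        pseudocount = 1.0 / (10.0 * free.n_bins)
    num = bound.values + pseudocount
    den = free.values + pseudocount
    if np.any(den <= 0) or np.any(num <= 0):
        raise ProfileError(
            "nonpositive profile bin with zero pseudocount; log ratio undefined"
        )
    return np.log2(num / den)


@dataclass
class ProtectionCall:
    """The protected-window decision for one strand."""

    parent_id: str
    scores: np.ndarray
    window: tuple[int, int] | None  # (start bond, end bond), 1-based inclusive
    threshold: float
    min_run: int

    @property
    def protected(self) -> bool:
        return self.window is not None


def call_protected_window(
    scores: np.ndarray,
    threshold: float = -1.0,
    min_run: int = 3,
    parent_id: str = "",
) -> ProtectionCall:
    """Longest maximal run of bonds with score < threshold, length >= min_run.

    Ties on length are broken by the most negative mean score.  Returns a
    call with ``window=None`` when no qualifying run exists.
    """
    scores = np.asarray(scores, dtype=float)
    below = scores < threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(below) - 1))
    runs = [(s, e) for s, e in runs if e - s + 1 >= min_run]
    if not runs:
        return ProtectionCall(parent_id, scores, None, threshold, min_run)
    best = min(
        runs,
        key=lambda r: (-(r[1] - r[0] + 1), float(np.mean(scores[r[0] : r[1] + 1]))),
    )
    window = (best[0] + 1, best[1] + 1)  # bonds are 1-based
    return ProtectionCall(parent_id, scores, window, threshold, min_run)


def footprint(
    free_peaks: PeakList,
    bound_peaks: PeakList,
    parent: ModifiedOligo,
    tol_ppm: float = 25.0,
    charges: Sequence[int] = (1, 2, 3, 4, 5, 6),
    threshold: float = -1.0,
    min_run: int = 3,
    pseudocount: float | None = None,
    scale: Scale = "monoisotopic",
) -> ProtectionCall:
    """End-to-end footprint on one strand: match, profile, score, call."""
    frags = enumerate_fragments(parent)
    prof_free = build_profile(
        match_peaks(free_peaks, frags, tol_ppm, charges, scale), parent
    )
    prof_bound = build_profile(
        match_peaks(bound_peaks, frags, tol_ppm, charges, scale), parent
    )
    scores = protection_score(prof_free, prof_bound, pseudocount)
    return call_protected_window(scores, threshold, min_run, parent.id)
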