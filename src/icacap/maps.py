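"""CAP brain-map reconstruction and cross-session component matching.

A fitted projection ``gamma_c`` lives in component space; its voxel-space
map is the corresponding row of ``Omega = Gamma^T S``.  Because neither
ICA nor CAP identifies signs, maps and loadings are canonicalized
(largest-magnitude loading positive) and cross-session comparisons use
absolute correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .capreg import CAPError, _canonical_sign

#: loadings with magnitude above this are a component's dominant ICs
DEFAULT_LOADING_THRESHOLD = 0.15
#: |standardized map value| above this is highlighted for display
DEFAULT_MAP_Z_THRESHOLD = 2.0


@dataclass
class BrainMaps:
    """Reconstructed covariate-related maps ``Omega = Gamma^T S``.

    ``loading_profiles`` holds the gamma columns transposed (R x K);
    ``highlighted_ics`` the 0-based indices with |loading| above the
    threshold, per component.
    """

    Omega: np.ndarray
    loading_profiles: np.ndarray
    highlighted_ics: list[list[int]]
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD
    map_z_threshold: float = DEFAULT_MAP_Z_THRESHOLD
    meta: dict = field(default_factory=dict)

    @property
    def R(self) -> int:
        return self.Omega.shape[0]

    @property
    def V(self) -> int:
        return self.Omega.shape[1]

    def thresholded(self, z: float | None = None) -> np.ndarray:
        """Display mask: standardize each row over voxels, keep |value| > z."""
        z = self.map_z_threshold if z is None else z
        O = self.Omega
        Ostd = (O - O.mean(axis=1, keepdims=True)) / O.std(
            axis=1, keepdims=True
        )
        return np.abs(Ostd) > z


def reconstruct_maps(
    Gamma: np.ndarray,
    S: np.ndarray,
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD,
    meta: dict | None = None,
) -> BrainMaps:
    """Compute ``Omega = Gamma^T S`` with loading profiles and highlights."""
    Gamma = np.asarray(Gamma, dtype=float)
    if Gamma.ndim == 1:
        Gamma = Gamma[:, None]
    S = np.asarray(S, dtype=float)
    if Gamma.shape[0] != S.shape[0]:
        raise CAPError(
            f"Gamma has {Gamma.shape[0]} rows, S has {S.shape[0]} rows"
        )
    Omega = Gamma.T @ S
    profiles = Gamma.T
    return BrainMaps(
        Omega=Omega,
        loading_profiles=profiles,
        highlighted_ics=loading_profile(Gamma, threshold=loading_threshold),
        loading_threshold=loading_threshold,
        meta=meta or {},
    )


def loading_profile(
    Gamma: np.ndarray, threshold: float = DEFAULT_LOADING_THRESHOLD
) -> list[list[int]]:
    """Indices with |loading| strictly above the threshold, per component."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    Gamma = np.asarray(Gamma, dtype=float)
    if Gamma.ndim == 1:
        Gamma = Gamma[:, None]
    return [
        sorted(np.nonzero(np.abs(Gamma[:, c]) > threshold)[0].tolist())
        for c in range(Gamma.shape[1])
    ]


def canonicalize_sign(obj):
    """Flip vectors/maps so each one's largest-|entry| element is positive.

    Accepts a vector, a K x R column matrix of loadings, or a
    :class:`BrainMaps` (where each gamma row and its map row flip
    together).  Idempotent; exact opposite-sign ties resolve to the
    lowest index.
    """
    if isinstance(obj, BrainMaps):
        profiles = obj.loading_profiles.copy()
        Omega = obj.Omega.copy()
        for c in range(profiles.shape[0]):
            flipped = _canonical_sign(profiles[c])
            if not np.array_equal(flipped, profiles[c]):
                Omega[c] = -Omega[c]
            profiles[c] = flipped
        return BrainMaps(
            Omega=Omega,
            loading_profiles=profiles,
            highlighted_ics=obj.highlighted_ics,
            loading_threshold=obj.loading_threshold,
            map_z_threshold=obj.map_z_threshold,
            meta=dict(obj.meta),
        )
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 1:
        return _canonical_sign(arr)
    out = arr.copy()
    for c in range(arr.shape[1]):
        out[:, c] = _canonical_sign(arr[:, c])
    return out


@dataclass
class MatchReport:
    """Cross-session component correspondence on loading vectors."""

    corr: np.ndarray  # (R1, R2) absolute correlations
    edges: list[tuple[int, int]]  # |corr| > threshold
    greedy_matching: list[tuple[int, int, float]]  # one-to-one, by |corr|
    threshold: float


def match_components(
    Gamma_a: np.ndarray,
    Gamma_b: np.ndarray,
    corr_threshold: float = 0.5,
) -> MatchReport:
    """Match components of two sessions by absolute loading correlation.

    Reports all pairs with |corr| above the threshold plus an optimal
    one-to-one assignment (maximum total |corr|, Hungarian algorithm).
    """
    Ga = np.asarray(Gamma_a, dtype=float)
    Gb = np.asarray(Gamma_b, dtype=float)
    if Ga.ndim == 1:
        Ga = Ga[:, None]
    if Gb.ndim == 1:
        Gb = Gb[:, None]
    if Ga.shape[0] != Gb.shape[0]:
        raise CAPError(
            f"sessions disagree on K: {Ga.shape[0]} vs {Gb.shape[0]}"
        )
    Ra, Rb = Ga.shape[1], Gb.shape[1]
    corr = np.empty((Ra, Rb))
    for a in range(Ra):
        for b in range(Rb):
            corr[a, b] = abs(np.corrcoef(Ga[:, a], Gb[:, b])[0, 1])
    edges = [
        (a, b) for a in range(Ra) for b in range(Rb)
        if corr[a, b] > corr_threshold
    ]
    row, col = linear_sum_assignment(-corr)
    matching = [(int(a), int(b), float(corr[a, b])) for a, b in zip(row, col)]
    return MatchReport(
        corr=corr, edges=edges, greedy_matching=matching,
        threshold=corr_threshold,
    )
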