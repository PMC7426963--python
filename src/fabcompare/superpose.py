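"""Rigid-body superposition (Kabsch) and backbone RMSD.

Two structures being compared are treated as rigid bodies and overlapped
using rotations and translations only; the residual deviation is

    RMSD = sqrt( (1/N) * sum_i |r_i,A - r_i,F|^2 )

over the N corresponding backbone atoms of the antigen-bound (A) and free
(F) forms.  The optimal overlap is computed with the Kabsch algorithm
(SVD with a determinant correction so that reflections are never used).

A fit may be computed over any residue *scope* (the entire chain or a
single domain) and the resulting transform applied to the whole chain, so
out-of-scope deviations can be measured under an in-scope overlap — the
operation behind both the per-domain RMSD table and the RMSF profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateError, ShapeError
from .structure_io import BACKBONE_ATOMS, ChainModel

Span = tuple[int, int]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mobile -> reference, and its residual RMSD."""

    rotation: np.ndarray       # 3x3 proper orthonormal
    translation: np.ndarray    # 3-vector, Å
    rmsd: float                # Å, over the fitted atom set
    n_atoms: int
    scope: str = "entire"
    n_residues_dropped: int = 0   # residues skipped for missing backbone atoms

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (N, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd_A": self.rmsd,
            "n_atoms": self.n_atoms,
            "scope": self.scope,
            "n_residues_dropped": self.n_residues_dropped,
        }


def _as_coords(x: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ShapeError(f"{name}: expected (N, 3) coordinates, got {arr.shape}")
    return arr


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Plain RMSD between corresponding atoms; no fitting performed."""
    a = _as_coords(coords_a, "coords_a")
    b = _as_coords(coords_b, "coords_b")
    if a.shape != b.shape:
        raise ShapeError(f"atom count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise ShapeError("RMSD undefined for empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def fit(coords_mobile: np.ndarray, coords_ref: np.ndarray,
        scope: str = "entire") -> SuperpositionResult:
    """Least-RMSD rigid superposition of ``coords_mobile`` onto ``coords_ref``.

    Kabsch algorithm: centre both sets, SVD of the covariance, and flip the
    smallest singular direction if the rotation would otherwise be improper.

    Raises
    ------
    DegenerateError
        For fewer than 3 points or (near-)collinear/coincident point sets,
        where the rotation is not uniquely determined.
    """
    mobile = _as_coords(coords_mobile, "coords_mobile")
    ref = _as_coords(coords_ref, "coords_ref")
    if mobile.shape != ref.shape:
        raise ShapeError(f"atom count mismatch: {mobile.shape[0]} vs {ref.shape[0]}")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateError(f"need at least 3 points to fit, got {n}")
    cm = mobile.mean(axis=0)
    cr = ref.mean(axis=0)
    pm = mobile - cm
    pr = ref - cr
    for pts, label in ((pm, "mobile"), (pr, "reference")):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DegenerateError(f"{label} points are collinear or coincident")
    h = pm.T @ pr
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    residual = rmsd(mobile @ rotation.T + translation, ref)
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=residual,
        n_atoms=n,
        scope=scope,
    )


def matched_backbone(
    chain_a: ChainModel,
    chain_b: ChainModel,
    indices: list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int], list[int]]:
    """Pair backbone atoms of two same-sequence chains by seq_index and name.

    Residues missing a backbone atom in either chain contribute only the
    atoms present in both; residues with no shared backbone atoms are
    dropped pairwise.  Returns the two (N, 3) arrays, the per-atom residue
    index, and the list of dropped residue indices.
    """
    if indices is None:
        indices = list(range(1, min(len(chain_a), len(chain_b)) + 1))
    ca, cb, owner, dropped = [], [], [], []
    for i in indices:
        if i > len(chain_a) or i > len(chain_b):
            continue
        ra = chain_a.residue(i).backbone_coords
        rb = chain_b.residue(i).backbone_coords
        names = [n for n in BACKBONE_ATOMS if n in ra and n in rb]
        if not names:
            dropped.append(i)
            continue
        for n in names:
            ca.append(ra[n])
            cb.append(rb[n])
            owner.append(i)
    if not ca:
        raise ShapeError("no shared backbone atoms in the requested scope")
    return np.array(ca), np.array(cb), owner, dropped


def fit_scope(
    free: ChainModel | list[ChainModel],
    bound: ChainModel | list[ChainModel],
    scope: Span | None = None,
    scope_label: str = "entire",
) -> SuperpositionResult:
    """Fit bound onto free using only backbone atoms of residues in ``scope``.

    ``free``/``bound`` may be single chains or lists of chains (the latter
    gives the joint whole-Fab overlap over both chains); the returned
    transform applies to any coordinates of the bound structure.
    """
    frees = free if isinstance(free, list) else [free]
    bounds = bound if isinstance(bound, list) else [bound]
    if len(frees) != len(bounds):
        raise ShapeError("free and bound must have the same number of chains")
    mob, ref, dropped_total = [], [], 0
    for f, b in zip(frees, bounds):
        idx = None
        if scope is not None:
            lo, hi = scope
            idx = list(range(lo, min(hi, len(f), len(b)) + 1))
        cb, cf, _, dropped = matched_backbone(b, f, idx)
        mob.append(cb)
        ref.append(cf)
        dropped_total += len(dropped)
    result = fit(np.concatenate(mob), np.concatenate(ref), scope=scope_label)
    result.n_residues_dropped = dropped_total
    return result


def scoped_rmsd(
    free: ChainModel,
    bound: ChainModel,
    transform: SuperpositionResult,
    span: Span,
) -> tuple[float, int]:
    """RMSD over ``span`` after applying an already-fitted transform.

    Used for per-domain cells of the RMSD table, where domains are *not*
    separately optimised: the transform comes from the whole-Fab overlap.
    Returns (rmsd, n_atoms).
    """
    lo, hi = span
    idx = list(range(lo, min(hi, len(free), len(bound)) + 1))
    cb, cf, _, _ = matched_backbone(bound, free, idx)
    return rmsd(transform.transform(cb), cf), cb.shape[0]
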