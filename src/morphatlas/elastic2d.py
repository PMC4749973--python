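"""Pair-wise consistent elastic 2D registration on cubic B-spline lattices.

Transforms follow the backward/resampling convention: a transform ``T`` maps
TARGET pixel coordinates to SOURCE pixel coordinates, ``T(p) = p + d(p)``,
where ``d`` is the cubic B-spline interpolation of a lattice of displacement
coefficients spread over the image extent.  Warping is ``out(p) = img(T(p))``.

The registration energy is a self-contained design: mean squared intensity
difference (both directions when the consistency weight is positive), a
first-order inverse-consistency penalty on the paired displacement fields,
and bending-energy regularization, minimized coarse-to-fine over a control
grid pyramid with L-BFGS-B and analytic gradients.  The finest grid density
depends only on the configured interval count and the image extent, never on
image content, so coefficient lattices from different pairs are always
average-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage, optimize, sparse


# ---------------------------------------------------------------------------
# cubic B-spline basis
# ---------------------------------------------------------------------------

def _basis_values(t: np.ndarray) -> np.ndarray:
    """The four active cubic B-spline basis weights at fraction t in [0, 1]."""
    t = np.asarray(t, dtype=float)
    omt = 1.0 - t
    return np.stack(
        [
            omt ** 3 / 6.0,
            (3 * t ** 3 - 6 * t ** 2 + 4) / 6.0,
            (-3 * t ** 3 + 3 * t ** 2 + 3 * t + 1) / 6.0,
            t ** 3 / 6.0,
        ]
    )


def _basis_d1(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.stack(
        [
            -((1.0 - t) ** 2) / 2.0,
            1.5 * t ** 2 - 2.0 * t,
            (-9 * t ** 2 + 6 * t + 3) / 6.0,
            t ** 2 / 2.0,
        ]
    )


def _basis_d2(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.stack([1.0 - t, 3.0 * t - 2.0, 1.0 - 3.0 * t, t])


_BASIS = {0: _basis_values, 1: _basis_d1, 2: _basis_d2}


def _lattice_coords(u: np.ndarray, extent: int, intervals: int) -> tuple[np.ndarray, np.ndarray]:
    """Map pixel coordinates to (cell index, fraction) on the control lattice."""
    span = max(extent - 1, 1)
    s = np.asarray(u, dtype=float) * intervals / span
    cell = np.clip(np.floor(s).astype(int), 0, intervals - 1)
    return cell, s - cell


# ---------------------------------------------------------------------------
# transform type
# ---------------------------------------------------------------------------

@dataclass
class BSplineGrid2D:
    """2D elastic transform as a lattice of (du, dv) coefficients in pixels."""

    coeffs: np.ndarray  # (gu, gv, 2)
    image_extent: tuple[int, int]
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[2] != 2:
            raise ValueError(f"coeffs must have shape (gu, gv, 2), got {self.coeffs.shape}")
        gu, gv, _ = self.coeffs.shape
        if gu < 4 or gv < 4:
            raise ValueError("cubic support requires gu, gv >= 4")
        self.image_extent = (int(self.image_extent[0]), int(self.image_extent[1]))
        if min(self.image_extent) < 1:
            raise ValueError("image extent must be positive")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def intervals(self) -> tuple[int, int]:
        return (self.coeffs.shape[0] - 3, self.coeffs.shape[1] - 3)

    def copy(self) -> "BSplineGrid2D":
        return replace(self, coeffs=self.coeffs.copy())


def grid_shape_for(extent: tuple[int, int], final_grid_intervals: int) -> tuple[int, int]:
    """Control intervals per axis: the longer in-plane axis gets the configured
    count, the shorter one a proportional count (>= 1). Content-independent."""
    nu, nv = extent
    longer = max(nu, nv)
    mu = max(1, round(final_grid_intervals * nu / longer))
    mv = max(1, round(final_grid_intervals * nv / longer))
    return mu, mv


def zero_transform(
    extent: tuple[int, int],
    final_grid_intervals: int = 8,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> BSplineGrid2D:
    mu, mv = grid_shape_for(extent, final_grid_intervals)
    return BSplineGrid2D(np.zeros((mu + 3, mv + 3, 2)), extent, pixel_spacing)


@dataclass
class ElasticParams:
    """Knobs of the pair-wise elastic step; every default is self-defined."""

    final_grid_intervals: int = 8
    pyramid_levels: int = 3
    similarity_weight: float = 1.0
    consistency_weight: float = 1.0
    regularization_weight: float = 0.1
    max_optimizer_steps: int = 200
    tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if min(self.similarity_weight, self.consistency_weight, self.regularization_weight) < 0:
            raise ValueError("energy weights must be >= 0")
        if self.final_grid_intervals < 1:
            raise ValueError("final_grid_intervals must be >= 1")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _displacement(t: BSplineGrid2D, pts: np.ndarray) -> np.ndarray:
    """Vectorized displacement lookup; pts (N, 2) in pixels, no bounds check."""
    nu, nv = t.image_extent
    mu, mv = t.intervals
    iu, fu = _lattice_coords(pts[:, 0], nu, mu)
    iv, fv = _lattice_coords(pts[:, 1], nv, mv)
    wu = _basis_values(fu)  # (4, N)
    wv = _basis_values(fv)
    out = np.zeros((pts.shape[0], 2))
    for l in range(4):
        for m in range(4):
            out += (wu[l] * wv[m])[:, None] * t.coeffs[iu + l, iv + m]
    return out


def displacement_at(t: BSplineGrid2D, p) -> np.ndarray:
    """Displacement (du, dv) at pixel point(s) ``p`` inside the image extent."""
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    nu, nv = t.image_extent
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > nu - 1) or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > nv - 1):
        raise ValueError("point outside image extent")
    out = _displacement(t, pts)
    return out[0] if np.asarray(p).ndim == 1 else out


def mean_transforms(ts: list[BSplineGrid2D]) -> BSplineGrid2D:
    """Element-wise arithmetic mean of coefficient lattices."""
    if not ts:
        raise ValueError("mean_transforms requires a nonempty list")
    first = ts[0]
    for t in ts[1:]:
        if t.coeffs.shape != first.coeffs.shape:
            raise ValueError("coefficient lattice shapes differ")
        if t.image_extent != first.image_extent or t.pixel_spacing != first.pixel_spacing:
            raise ValueError("image extent / spacing mismatch")
    coeffs = np.mean([t.coeffs for t in ts], axis=0)
    return BSplineGrid2D(coeffs, first.image_extent, first.pixel_spacing)


def warp_coords(t: BSplineGrid2D) -> np.ndarray:
    """Sampling coordinates (2, nu, nv): where each target pixel reads from."""
    nu, nv = t.image_extent
    bu, bv = np.meshgrid(np.arange(nu, dtype=float), np.arange(nv, dtype=float), indexing="ij")
    pts = np.stack([bu.ravel(), bv.ravel()], axis=1)
    d = _displacement(t, pts)
    return np.stack([bu + d[:, 0].reshape(nu, nv), bv + d[:, 1].reshape(nu, nv)])


def warp_image(img: np.ndarray, t: BSplineGrid2D, interp: str = "linear") -> np.ndarray:
    """Resample ``img`` through ``t``: out(p) = img(T(p)); out-of-bounds -> 0."""
    img = np.asarray(img)
    if img.shape != t.image_extent:
        raise ValueError(f"image shape {img.shape} != transform extent {t.image_extent}")
    order = {"nearest": 0, "linear": 1}[interp]
    return ndimage.map_coordinates(img.astype(float), warp_coords(t), order=order, mode="constant", cval=0.0)


def warp_label_image(img: np.ndarray, t: BSplineGrid2D) -> np.ndarray:
    """Binary warp: linear interpolation followed by a 0.5 threshold."""
    return (warp_image(img, t, interp="linear") > 0.5).astype(np.uint8)


class InversionError(RuntimeError):
    def __init__(self, q, residual, tol):
        super().__init__(f"transform inversion did not converge at {q}: residual {residual:.3g} > tol {tol:.3g}")
        self.residual = residual


def invert_point(t: BSplineGrid2D, q, tol: float = 1e-3, max_iter: int = 50) -> np.ndarray:
    """Find p with T(p) = q by fixed-point iteration p <- q - d(p).

    The returned p is where content originally at q appears after warping.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    pts = np.atleast_2d(q)
    p = pts.copy()
    nu, nv = t.image_extent
    for _ in range(max_iter):
        clamped = np.clip(p, 0.0, [nu - 1, nv - 1])
        d = _displacement(t, clamped)
        new_p = pts - d
        if np.max(np.abs(new_p - p)) <= tol * 0.1:
            p = new_p
            break
        p = new_p
    resid = np.linalg.norm(p + _displacement(t, np.clip(p, 0.0, [nu - 1, nv - 1])) - pts, axis=1)
    worst = float(resid.max())
    if worst > tol:
        raise InversionError(pts[int(resid.argmax())], worst, tol)
    return p[0] if single else p


# ---------------------------------------------------------------------------
# registration machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _basis_matrices(extent: tuple[int, int], intervals: tuple[int, int]):
    """Sparse pixel->coefficient basis matrices for value and 2nd derivatives.

    Returns (B, K) with B the (N, G) interpolation matrix and K the (G, G)
    bending-energy quadratic form (already averaged over pixels).
    """
    nu, nv = extent
    mu, mv = intervals
    gu, gv = mu + 3, mv + 3
    bu, bv = np.meshgrid(np.arange(nu, dtype=float), np.arange(nv, dtype=float), indexing="ij")
    uu, vv = bu.ravel(), bv.ravel()
    n = uu.size
    iu, fu = _lattice_coords(uu, nu, mu)
    iv, fv = _lattice_coords(vv, nv, mv)
    su = mu / max(nu - 1, 1)  # d(lattice)/d(pixel) scale per axis
    sv = mv / max(nv - 1, 1)

    def build(du: int, dv: int) -> sparse.csr_matrix:
        wu = _BASIS[du](fu) * su ** du
        wv = _BASIS[dv](fv) * sv ** dv
        rows = np.repeat(np.arange(n), 16)
        cols = np.empty((n, 16), dtype=int)
        vals = np.empty((n, 16))
        k = 0
        for l in range(4):
            for m in range(4):
                cols[:, k] = (iu + l) * gv + (iv + m)
                vals[:, k] = wu[l] * wv[m]
                k += 1
        mat = sparse.csr_matrix((vals.ravel(), (rows, cols.ravel())), shape=(n, gu * gv))
        mat.sum_duplicates()
        return mat

    B = build(0, 0)
    Muu = build(2, 0)
    Muv = build(1, 1)
    Mvv = build(0, 2)
    K = (Muu.T @ Muu + 2.0 * (Muv.T @ Muv) + Mvv.T @ Mvv) / n
    return B, sparse.csr_matrix(K)


def _sample_bilinear(img_padded: np.ndarray, u: np.ndarray, v: np.ndarray):
    """Bilinear sample with exact in-cell gradients; coords in padded frame."""
    nu, nv = img_padded.shape
    u = np.clip(u, 0.0, nu - 1.0)
    v = np.clip(v, 0.0, nv - 1.0)
    u0 = np.minimum(u.astype(int), nu - 2)
    v0 = np.minimum(v.astype(int), nv - 2)
    fu = u - u0
    fv = v - v0
    i00 = img_padded[u0, v0]
    i10 = img_padded[u0 + 1, v0]
    i01 = img_padded[u0, v0 + 1]
    i11 = img_padded[u0 + 1, v0 + 1]
    val = (1 - fu) * (1 - fv) * i00 + fu * (1 - fv) * i10 + (1 - fu) * fv * i01 + fu * fv * i11
    gu = (1 - fv) * (i10 - i00) + fv * (i11 - i01)
    gv = (1 - fu) * (i01 - i00) + fu * (i11 - i10)
    return val, gu, gv


class _PairEnergy:
    """Joint energy for one (optionally bidirectional) pair at one grid level."""

    def __init__(self, src: np.ndarray, tgt: np.ndarray, intervals: tuple[int, int], params: ElasticParams):
        self.extent = src.shape
        nu, nv = self.extent
        self.n = nu * nv
        self.params = params
        self.bidirectional = params.consistency_weight > 0
        self.B, self.K = _basis_matrices(self.extent, intervals)
        self.g = self.B.shape[1]
        bu, bv = np.meshgrid(np.arange(nu, dtype=float), np.arange(nv, dtype=float), indexing="ij")
        self.baseu = bu.ravel() + 1.0  # +1: padded-image frame
        self.basev = bv.ravel() + 1.0
        self.srcp = np.pad(src.astype(float), 1)
        self.tgtp = np.pad(tgt.astype(float), 1)
        self.src_flat = src.astype(float).ravel()
        self.tgt_flat = tgt.astype(float).ravel()

    def _direction_terms(self, cu, cv, moving_padded, fixed_flat):
        """Similarity + its gradient for one resampling direction."""
        du = self.B @ cu
        dv = self.B @ cv
        val, gu, gv = _sample_bilinear(moving_padded, self.baseu + du, self.basev + dv)
        r = val - fixed_flat
        e = float(r @ r) / self.n
        scale = 2.0 / self.n
        return e, scale * (self.B.T @ (r * gu)), scale * (self.B.T @ (r * gv)), du, dv

    def __call__(self, x: np.ndarray):
        p = self.params
        g = self.g
        cTu, cTv = x[:g], x[g : 2 * g]
        grad = np.zeros_like(x)
        eT, gTu, gTv, dTu, dTv = self._direction_terms(cTu, cTv, self.srcp, self.tgt_flat)
        energy = p.similarity_weight * eT
        grad[:g] += p.similarity_weight * gTu
        grad[g : 2 * g] += p.similarity_weight * gTv
        # bending regularization (per direction)
        for off, c in ((0, cTu), (g, cTv)):
            energy += p.regularization_weight * float(c @ (self.K @ c))
            grad[off : off + g] += p.regularization_weight * 2.0 * (self.K @ c)
        if self.bidirectional:
            cUu, cUv = x[2 * g : 3 * g], x[3 * g :]
            eU, gUu, gUv, dUu, dUv = self._direction_terms(cUu, cUv, self.tgtp, self.src_flat)
            energy += p.similarity_weight * eU
            grad[2 * g : 3 * g] += p.similarity_weight * gUu
            grad[3 * g :] += p.similarity_weight * gUv
            for off, c in ((2 * g, cUu), (3 * g, cUv)):
                energy += p.regularization_weight * float(c @ (self.K @ c))
                grad[off : off + g] += p.regularization_weight * 2.0 * (self.K @ c)
            # first-order inverse consistency: d_T + d_U ~ 0
            su = dTu + dUu
            sv = dTv + dUv
            energy += p.consistency_weight * (float(su @ su) + float(sv @ sv)) / self.n
            cg_u = p.consistency_weight * 2.0 / self.n * (self.B.T @ su)
            cg_v = p.consistency_weight * 2.0 / self.n * (self.B.T @ sv)
            grad[:g] += cg_u
            grad[g : 2 * g] += cg_v
            grad[2 * g : 3 * g] += cg_u
            grad[3 * g :] += cg_v
        return energy, grad


def _refine_coeffs(t: BSplineGrid2D, intervals: tuple[int, int]) -> np.ndarray:
    """Initialize a denser lattice by sampling the current displacement field
    at the new control anchors (approximate, used only as optimizer init)."""
    nu, nv = t.image_extent
    mu, mv = intervals
    gu, gv = mu + 3, mv + 3
    au = np.clip((np.arange(gu) - 1.0) * (nu - 1) / mu, 0, nu - 1)
    av = np.clip((np.arange(gv) - 1.0) * (nv - 1) / mv, 0, nv - 1)
    pu, pv = np.meshgrid(au, av, indexing="ij")
    pts = np.stack([pu.ravel(), pv.ravel()], axis=1)
    return _displacement(t, pts).reshape(gu, gv, 2)


def _level_plan(final_intervals: tuple[int, int], levels: int) -> list[tuple[int, tuple[int, int]]]:
    plan = []
    for lev in range(levels):
        factor = 2 ** (levels - 1 - lev)
        mu = max(1, int(np.ceil(final_intervals[0] / factor)))
        mv = max(1, int(np.ceil(final_intervals[1] / factor)))
        plan.append((factor, (mu, mv)))
    # drop duplicated coarse levels (tiny images)
    dedup = []
    for entry in plan:
        if not dedup or dedup[-1][1] != entry[1]:
            dedup.append(entry)
    return dedup


def register_pair_both(
    source: np.ndarray,
    target: np.ndarray,
    params: ElasticParams | None = None,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> tuple[BSplineGrid2D, BSplineGrid2D]:
    """Jointly estimate T (resamples source toward target) and U (the reverse).

    ``register_pair_both(a, b)[0]`` equals ``register_pair(a, b)`` and
    ``[1]`` equals ``register_pair(b, a)``; one joint solve serves both.
    """
    params = params or ElasticParams()
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError(f"extent mismatch: {source.shape} vs {target.shape}")
    if not (np.all(np.isfinite(source)) and np.all(np.isfinite(target))):
        raise ValueError("images must be finite")
    extent = source.shape
    final = grid_shape_for(extent, params.final_grid_intervals)
    bidir = params.consistency_weight > 0

    t_cur: BSplineGrid2D | None = None
    u_cur: BSplineGrid2D | None = None
    for factor, intervals in _level_plan(final, params.pyramid_levels):
        if factor > 1:
            src_l = ndimage.gaussian_filter(source, sigma=factor / 2.0)
            tgt_l = ndimage.gaussian_filter(target, sigma=factor / 2.0)
        else:
            src_l, tgt_l = source, target
        energy = _PairEnergy(src_l, tgt_l, intervals, params)
        g = energy.g
        if t_cur is None:
            x0 = np.zeros(4 * g if bidir else 2 * g)
        else:
            ct = _refine_coeffs(t_cur, intervals)
            parts = [ct[..., 0].ravel(), ct[..., 1].ravel()]
            if bidir:
                cu = _refine_coeffs(u_cur, intervals)
                parts += [cu[..., 0].ravel(), cu[..., 1].ravel()]
            x0 = np.concatenate(parts)
        res = optimize.minimize(
            energy,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": params.max_optimizer_steps, "ftol": params.tolerance},
        )
        x = res.x
        gu, gv = intervals[0] + 3, intervals[1] + 3
        t_cur = BSplineGrid2D(
            np.stack([x[:g].reshape(gu, gv), x[g : 2 * g].reshape(gu, gv)], axis=-1), extent, pixel_spacing
        )
        if bidir:
            u_cur = BSplineGrid2D(
                np.stack([x[2 * g : 3 * g].reshape(gu, gv), x[3 * g :].reshape(gu, gv)], axis=-1),
                extent,
                pixel_spacing,
            )
    # with consistency off the reverse direction is simply not estimated
    return t_cur, u_cur


def register_pair(
    source: np.ndarray,
    target: np.ndarray,
    params: ElasticParams | None = None,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> BSplineGrid2D:
    """Estimate the B-spline transform resampling ``source`` toward ``target``."""
    t, _ = register_pair_both(source, target, params, pixel_spacing)
    return t
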