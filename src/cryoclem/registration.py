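"""Control-point transform estimation and registration error metrics.

This is the computational heart of the multi-scale correlation workflow:

* channel-shift correction between fluorescence channels (multicolor bead
  field, default affine model),
* the coarse stage — 200 nm beads shared between the fluorescence image and
  the EM montage map (default similarity model),
* the fine stage — 50 nm gold shared between the montage and the tomogram
  z-projection,
* composition of the two stages into a single FM -> tomogram mapping.

Least-squares fits are closed-form: translation is the weighted mean
displacement, rigid/similarity use the orthogonal-Procrustes solution
(reflections allowed, recorded in the determinant sign), affine solves
weighted normal equations on centered coordinates.  Fit quality is reported
as the RMS fiducial registration error (FRE) and a leave-one-out target
registration error (TRE) estimate per point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .detection import FiducialDetection
from .geometry import (
    Correspondence,
    Point2D,
    PointSet,
    Transform2D,
    as_xy_array,
    compose_transforms,
)

__all__ = [
    "RegistrationResult",
    "CorrelationChain",
    "MIN_POINTS",
    "estimate_transform",
    "estimate_transform_robust",
    "estimate_channel_shift",
    "match_correspondences",
    "build_chain",
]

#: minimum correspondence count per transform family
MIN_POINTS = {"translation": 1, "rigid": 2, "similarity": 2, "affine": 3}

_DEGENERACY_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when the control points cannot constrain the requested model."""


@dataclass
class RegistrationResult:
    """A fitted transform together with its per-point diagnostics.

    ``residuals_px`` are target-frame 2-vectors ``T(source) - target``;
    ``fre_rms_px`` is the RMS of their norms (weighted when weights differ);
    ``loo_tre_px`` holds one leave-one-out prediction error per point, or is
    None when there are too few points to spare one.
    """

    transform: Transform2D
    correspondences: list[Correspondence]
    residuals_px: np.ndarray
    fre_rms_px: float
    loo_tre_px: np.ndarray | None = None
    inlier_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residuals_px = np.asarray(self.residuals_px, dtype=float).reshape(-1, 2)
        if len(self.residuals_px) != len(self.correspondences):
            raise ValueError("one residual per correspondence required")
        if self.fre_rms_px < 0:
            raise ValueError("fre_rms_px must be >= 0")

    @property
    def n_points(self) -> int:
        return len(self.correspondences)

    @property
    def mean_loo_tre_px(self) -> float | None:
        return None if self.loo_tre_px is None else float(np.mean(self.loo_tre_px))

    def to_dict(self) -> dict:
        d = {
            "transform": self.transform.to_dict(),
            "n_points": self.n_points,
            "fre_rms_px": self.fre_rms_px,
            "residuals_px": self.residuals_px.tolist(),
            "loo_tre_px": None if self.loo_tre_px is None else self.loo_tre_px.tolist(),
            "source_points": [[c.source.x, c.source.y] for c in self.correspondences],
            "target_points": [[c.target.x, c.target.y] for c in self.correspondences],
            "weights": [c.weight for c in self.correspondences],
        }
        if self.inlier_mask is not None:
            d["inlier_mask"] = [bool(v) for v in self.inlier_mask]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationResult":
        corrs = [
            Correspondence(Point2D(*s), Point2D(*t), w)
            for s, t, w in zip(d["source_points"], d["target_points"], d["weights"])
        ]
        return cls(
            transform=Transform2D.from_dict(d["transform"]),
            correspondences=corrs,
            residuals_px=np.asarray(d["residuals_px"], dtype=float),
            fre_rms_px=float(d["fre_rms_px"]),
            loo_tre_px=None if d.get("loo_tre_px") is None else np.asarray(d["loo_tre_px"], dtype=float),
            inlier_mask=None if d.get("inlier_mask") is None else np.asarray(d["inlier_mask"], dtype=bool),
        )


def _split(correspondences) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    src = as_xy_array([c.source for c in correspondences])
    dst = as_xy_array([c.target for c in correspondences])
    w = np.asarray([c.weight for c in correspondences], dtype=float)
    if w.sum() <= 0:
        raise ValueError("total correspondence weight must be positive")
    return src, dst, w


def _fit_matrix_offset(src: np.ndarray, dst: np.ndarray, w: np.ndarray, model: str) -> tuple[np.ndarray, np.ndarray]:
    """Weighted closed-form fit of the linear part + offset for one model."""
    wn = w / w.sum()
    mu_s = wn @ src
    mu_d = wn @ dst
    xs = src - mu_s
    xd = dst - mu_d

    if model == "translation":
        mat = np.eye(2)
    elif model in ("rigid", "similarity"):
        # weighted orthogonal Procrustes; reflections permitted (best orthogonal
        # factor U V^T of the cross-covariance, no determinant correction)
        cov = (xd * wn[:, None]).T @ xs  # maps source -> target
        u, sv, vt = np.linalg.svd(cov)
        if sv[0] <= _DEGENERACY_TOL * max(1.0, np.abs(xs).max(), np.abs(xd).max()):
            raise DegenerateGeometryError(
                f"points are coincident; {model} fit needs at least "
                f"{MIN_POINTS[model]} distinct positions"
            )
        rot = u @ vt
        if model == "similarity":
            var_s = float(np.sum(wn * np.sum(xs**2, axis=1)))
            if var_s <= 0:
                raise DegenerateGeometryError("source points are coincident; cannot estimate scale")
            mat = (sv.sum() / var_s) * rot
        else:
            mat = rot
    elif model == "affine":
        a = xs * np.sqrt(wn)[:, None]
        b = xd * np.sqrt(wn)[:, None]
        # rank check: collinear source points cannot constrain an affine map
        svals = np.linalg.svd(a, compute_uv=False)
        if svals[-1] <= _DEGENERACY_TOL * max(1.0, svals[0]):
            raise DegenerateGeometryError(
                "source points are collinear (rank-deficient); an affine fit needs "
                "3 non-collinear points"
            )
        mat, *_ = np.linalg.lstsq(a, b, rcond=None)
        mat = mat.T
    else:
        raise ValueError(f"unknown model {model!r}")

    offset = mu_d - mat @ mu_s
    return mat, offset


def estimate_transform(
    correspondences: list[Correspondence],
    model: str = "similarity",
    *,
    source_frame: str | None = None,
    target_frame: str | None = None,
    compute_loo: bool = True,
) -> RegistrationResult:
    """Weighted least-squares control-point fit with FRE and leave-one-out TRE.

    Raises :class:`DegenerateGeometryError` for configurations that cannot
    constrain the model (coincident points for similarity, collinear points
    for affine) and :class:`ValueError` when there are fewer correspondences
    than the model's minimum (1 translation, 2 rigid/similarity, 3 affine).
    """
    if model not in MIN_POINTS:
        raise ValueError(f"unknown model {model!r}; expected one of {tuple(MIN_POINTS)}")
    n = len(correspondences)
    if n < MIN_POINTS[model]:
        raise ValueError(
            f"{model} fit needs at least {MIN_POINTS[model]} correspondences, got {n}"
        )
    src, dst, w = _split(correspondences)
    mat, offset = _fit_matrix_offset(src, dst, w, model)
    transform = Transform2D(model, mat, offset, source_frame=source_frame, target_frame=target_frame)

    residuals = src @ mat.T + offset - dst
    wn = w / w.sum()
    fre = float(np.sqrt(np.sum(wn * np.sum(residuals**2, axis=1))))

    loo = None
    if compute_loo and n >= MIN_POINTS[model] + 1:
        loo = np.empty(n)
        idx = np.arange(n)
        for i in range(n):
            keep = idx != i
            try:
                m_i, o_i = _fit_matrix_offset(src[keep], dst[keep], w[keep], model)
            except DegenerateGeometryError:
                loo = None
                break
            loo[i] = np.linalg.norm(m_i @ src[i] + o_i - dst[i])

    return RegistrationResult(
        transform=transform,
        correspondences=list(correspondences),
        residuals_px=residuals,
        fre_rms_px=fre,
        loo_tre_px=loo,
    )


def estimate_transform_robust(
    correspondences: list[Correspondence],
    model: str = "similarity",
    *,
    inlier_threshold_px: float = 2.0,
    max_iterations: int = 500,
    seed: int,
    source_frame: str | None = None,
    target_frame: str | None = None,
) -> RegistrationResult:
    """RANSAC-style consensus fit, then a least-squares refit on the inliers.

    ``seed`` is required: all randomness is explicit.  The returned result
    carries an ``inlier_mask`` over the input correspondences; its FRE/TRE
    are computed on the inliers only.

    Raises :class:`ValueError` when no consensus of at least the model's
    minimum size (plus one, so the fit is over-determined) can be found.
    """
    n = len(correspondences)
    k = MIN_POINTS[model]
    if n < k:
        raise ValueError(f"{model} fit needs at least {k} correspondences, got {n}")
    src, dst, w = _split(correspondences)
    rng = np.random.default_rng(seed)

    best_mask: np.ndarray | None = None
    best_key = (-1, np.inf)  # (n_inliers, rms) — maximize count, then minimize rms
    for _ in range(max_iterations):
        sample = rng.choice(n, size=k, replace=False)
        try:
            mat, off = _fit_matrix_offset(src[sample], dst[sample], w[sample], model)
        except DegenerateGeometryError:
            continue
        res = np.linalg.norm(src @ mat.T + off - dst, axis=1)
        mask = res <= inlier_threshold_px
        if mask.sum() < max(k + 1, 3):
            continue
        key = (int(mask.sum()), float(np.sqrt(np.mean(res[mask] ** 2))))
        if key[0] > best_key[0] or (key[0] == best_key[0] and key[1] < best_key[1]):
            best_key, best_mask = key, mask

    if best_mask is None:
        raise ValueError(
            f"no consensus of >= {max(k + 1, 3)} inliers found within "
            f"{inlier_threshold_px} px; check the correspondences or the threshold"
        )

    # refit on consensus, then one re-consensus pass for stability
    for _ in range(2):
        inliers = [c for c, m in zip(correspondences, best_mask) if m]
        fit = estimate_transform(
            inliers, model, source_frame=source_frame, target_frame=target_frame
        )
        res = np.linalg.norm(fit.transform.apply(src) - dst, axis=1)
        new_mask = res <= inlier_threshold_px
        if new_mask.sum() < max(k + 1, 3) or np.array_equal(new_mask, best_mask):
            break
        best_mask = new_mask

    fit.inlier_mask = best_mask
    return fit


def estimate_channel_shift(
    ref_points: PointSet,
    moving_points: PointSet,
    model: str = "affine",
) -> RegistrationResult:
    """Chromatic/channel shift from a paired multicolor-bead field.

    The two point sets must list the same beads in the same order (one entry
    per bead, as picked in each imaging channel).  Returns the transform
    mapping the moving channel into the reference channel's frame; the
    default affine model absorbs the field-dependent component of chromatic
    shift, not just a rigid offset.
    """
    if len(ref_points) != len(moving_points):
        raise ValueError(
            f"paired channels must have equal counts (got {len(ref_points)} reference, "
            f"{len(moving_points)} moving)"
        )
    if len(ref_points) < MIN_POINTS[model]:
        raise ValueError(
            f"{model} channel-shift fit needs at least {MIN_POINTS[model]} bead pairs"
        )
    corrs = [
        Correspondence(Point2D(*m), Point2D(*r))
        for m, r in zip(moving_points.points, ref_points.points)
    ]
    return estimate_transform(
        corrs, model, source_frame=moving_points.frame_id, target_frame=ref_points.frame_id
    )


def _coords(items) -> np.ndarray:
    pts = [
        it.center if isinstance(it, FiducialDetection) else it
        for it in items
    ]
    return as_xy_array(pts)


def _mutual_nn(moved: np.ndarray, target: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    tree_t = cKDTree(target)
    tree_s = cKDTree(moved)
    d_st, j_st = tree_t.query(moved, k=1)
    _, i_ts = tree_s.query(target, k=1)
    pairs = [
        (i, int(j))
        for i, (d, j) in enumerate(zip(d_st, j_st))
        if d <= max_dist and i_ts[int(j)] == i
    ]
    return pairs


def match_correspondences(
    source,
    target,
    initial: Transform2D | None = None,
    max_dist_px: float = 5.0,
    *,
    min_matches: int = 3,
    allow_reflection: bool = True,
) -> list[Correspondence]:
    """One-to-one matching of two fiducial lists across modalities.

    With an ``initial`` transform, matching is mutual-nearest-neighbor after
    mapping the source points, keeping pairs within ``max_dist_px`` of each
    other (target-frame pixels).  Without one, a deterministic exhaustive
    hypothesis search over point-pair alignments is run: every source pair
    against every ordered target pair defines a candidate similarity (with
    and without reflection when ``allow_reflection``); the hypothesis with
    the largest mutual-NN consensus (ties: smaller consensus RMS, then
    enumeration order) wins and its consensus is refit before the final
    matching.  The search is intended for small sets (n <= 30).

    Items may be :class:`FiducialDetection` objects, ``Point2D`` or plain
    (x, y) pairs.  Raises :class:`ValueError` when no matching of at least
    ``min_matches`` pairs exists.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("source and target lists must be non-empty")
    src = _coords(source)
    dst = _coords(target)

    if initial is None:
        if len(src) > 30 or len(dst) > 30:
            raise ValueError(
                "hypothesis search is limited to sets of <= 30 points; supply an "
                "initial transform for larger sets"
            )
        initial = _hypothesis_search(src, dst, max_dist_px, min_matches, allow_reflection)

    pairs = _mutual_nn(initial.apply(src), dst, max_dist_px)
    if len(pairs) < min_matches:
        raise ValueError(
            f"only {len(pairs)} mutual matches within {max_dist_px} px; "
            f"need at least {min_matches}"
        )
    return [Correspondence(Point2D(*src[i]), Point2D(*dst[j])) for i, j in pairs]


def _pair_similarity(s0, s1, t0, t1, reflect: bool) -> tuple[complex, complex] | None:
    """Similarity mapping (s0,s1)->(t0,t1) as complex a*z+b (a*conj(z)+b if reflect)."""
    zs0, zs1 = complex(*s0), complex(*s1)
    zt0, zt1 = complex(*t0), complex(*t1)
    if reflect:
        zs0, zs1 = zs0.conjugate(), zs1.conjugate()
    denom = zs1 - zs0
    if denom == 0:
        return None
    a = (zt1 - zt0) / denom
    if a == 0:
        return None
    return a, zt0 - a * zs0


def _hypothesis_search(
    src: np.ndarray, dst: np.ndarray, max_dist: float, min_matches: int, allow_reflection: bool
) -> Transform2D:
    """Exhaustive pair-alignment search for the best similarity hypothesis."""
    zs = src[:, 0] + 1j * src[:, 1]
    zd = dst[:, 0] + 1j * dst[:, 1]
    ns, nt = len(src), len(dst)
    reflections = (False, True) if allow_reflection else (False,)

    best = None  # (count, -rms) maximized; then first in enumeration order
    for i in range(ns):
        for j in range(i + 1, ns):
            for k in range(nt):
                for l in range(nt):
                    if k == l:
                        continue
                    for refl in reflections:
                        ab = _pair_similarity(src[i], src[j], dst[k], dst[l], refl)
                        if ab is None:
                            continue
                        a, b = ab
                        moved = a * (np.conj(zs) if refl else zs) + b
                        d = np.abs(moved[:, None] - zd[None, :])
                        nn = d.min(axis=1)
                        inl = nn <= max_dist
                        cnt = int(inl.sum())
                        if cnt < max(min_matches, 2):
                            continue
                        rms = float(np.sqrt(np.mean(nn[inl] ** 2)))
                        key = (cnt, -rms)
                        if best is None or key > best[0]:
                            best = (key, a, b, refl)
    if best is None:
        raise ValueError(
            f"hypothesis search found no alignment with >= {min_matches} matches "
            f"within {max_dist} px"
        )
    _, a, b, refl = best
    mat = np.array([[a.real, -a.imag], [a.imag, a.real]])
    if refl:
        mat = mat @ np.diag([1.0, -1.0])  # conjugation = flip y before rotate/scale
    t = Transform2D("similarity", mat, np.array([b.real, b.imag]))
    # refine on the mutual-NN consensus of the winning hypothesis
    pairs = _mutual_nn(t.apply(src), dst, max_dist)
    if len(pairs) >= 2:
        corrs = [Correspondence(Point2D(*src[i]), Point2D(*dst[j])) for i, j in pairs]
        try:
            t = estimate_transform(corrs, "similarity", compute_loo=False).transform
        except DegenerateGeometryError:
            pass
    return t


@dataclass
class CorrelationChain:
    """The three-marker hierarchy composed into one FM -> tomogram mapping.

    ``fm_channel_shift`` maps the signal channel (e.g. PSD95) into the bead
    channel frame used for the coarse stage; ``fm_to_tomogram`` is the
    composition of the coarse (bead) and fine (gold) stages.
    ``predicted_error_px`` propagates the stages' mean leave-one-out TRE into
    tomogram pixels: coarse TRE scaled by the fine stage's magnification plus
    the fine TRE (in quadrature).
    """

    fm_channel_shift: Transform2D
    fm_to_montage: RegistrationResult
    montage_to_tomogram: RegistrationResult
    fm_to_tomogram: Transform2D = field(init=False)
    predicted_error_px: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        coarse_t = self.fm_to_montage.transform
        fine_t = self.montage_to_tomogram.transform
        if (
            coarse_t.target_frame is not None
            and fine_t.source_frame is not None
            and coarse_t.target_frame != fine_t.source_frame
        ):
            raise ValueError(
                f"stages are not chainable: coarse maps into frame "
                f"{coarse_t.target_frame!r} but fine starts from {fine_t.source_frame!r}"
            )
        self.fm_to_tomogram = compose_transforms(fine_t, coarse_t)
        tre_c = self.fm_to_montage.mean_loo_tre_px
        tre_f = self.montage_to_tomogram.mean_loo_tre_px
        if tre_c is not None and tre_f is not None:
            self.predicted_error_px = float(np.hypot(fine_t.scale * tre_c, tre_f))

    def map_fm_point(self, p, *, channel_shifted: bool = False) -> np.ndarray:
        """Map FM coordinates into the tomogram frame.

        With ``channel_shifted=False`` the point is assumed to be in the
        signal channel and is first moved into the bead-channel frame via
        ``fm_channel_shift``.
        """
        arr = as_xy_array(p)
        if not channel_shifted:
            arr = self.fm_channel_shift.apply(arr)
        out = self.fm_to_tomogram.apply(arr)
        return out[0] if np.asarray(p, dtype=float).ndim == 1 else out

    def to_dict(self) -> dict:
        return {
            "fm_channel_shift": self.fm_channel_shift.to_dict(),
            "fm_to_montage": self.fm_to_montage.to_dict(),
            "montage_to_tomogram": self.montage_to_tomogram.to_dict(),
            "fm_to_tomogram": self.fm_to_tomogram.to_dict(),
            "predicted_error_px": self.predicted_error_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationChain":
        return cls(
            fm_channel_shift=Transform2D.from_dict(d["fm_channel_shift"]),
            fm_to_montage=RegistrationResult.from_dict(d["fm_to_montage"]),
            montage_to_tomogram=RegistrationResult.from_dict(d["montage_to_tomogram"]),
        )


def build_chain(
    fm_shift: Transform2D,
    coarse: RegistrationResult,
    fine: RegistrationResult,
) -> CorrelationChain:
    """Compose the channel-shift, coarse (bead) and fine (gold) stages."""
    return CorrelationChain(
        fm_channel_shift=fm_shift, fm_to_montage=coarse, montage_to_tomogram=fine
    )
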