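"""Voxel-wise permutation inference with familywise error control.

Two tests are provided, mirroring standard permutation analysis of linear
models for lesion network mapping:

* :func:`one_sample_permutation` — is the across-lesion mean connectivity at
  each voxel nonzero? The null is generated by random sign flips of whole
  per-lesion maps (valid under symmetric errors); when ``2^n`` does not
  exceed the permutation budget all sign assignments are enumerated
  exhaustively and the p-values are exact.
* :func:`two_sample_permutation` — is connectivity specific to the symptom
  cohort relative to a library of comparison lesions grouped into syndromes?
  The statistic is a weighted Welch t in which every comparison syndrome
  receives equal total weight regardless of its size; the null permutes
  exchangeable blocks (each syndrome is one block, each sensory lesion its
  own block) between groups.

Familywise error is controlled per voxel by the permutation distribution of
the maximum statistic over the brain mask (strong control). Monte-Carlo
p-values use the Phipson–Smyth "+1" correction, p = (1 + b) / (1 + B), so
they are never exactly zero. For p-values far below 1/B a generalized Pareto
distribution is fitted to the extreme tail of the max-statistic null
(threshold at the upper ``gpd_tail_fraction`` of the null, maximum-likelihood
fit, Anderson–Darling goodness-of-fit gate with the Choulakian–Stephens
critical values); when no acceptable fit exists the empirical p is returned
unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .volumes import BinaryMask, ScalarMap, VolumeError, extract, insert

logger = logging.getLogger(__name__)

T_CAP = 1e6


@dataclass
class PermutationConfig:
    n_permutations: int = 2000
    seed: int = 0
    tail_approximation: bool = True
    fwe_alpha: float = 0.05
    gpd_tail_fraction: float = 0.10
    gpd_trigger_p: float = 0.075
    gof_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise VolumeError("n_permutations must be >= 1")
        if not 0 < self.fwe_alpha < 1:
            raise VolumeError("fwe_alpha must be in (0, 1)")
        if not 0 < self.gpd_tail_fraction < 0.5:
            raise VolumeError("gpd_tail_fraction must be in (0, 0.5)")


@dataclass
class StatMap:
    """Voxel-wise statistic plus FWE-corrected p maps with provenance."""

    stat: ScalarMap
    p_fwe: ScalarMap          # two-sided
    p_fwe_pos: ScalarMap      # positive tail
    p_fwe_neg: ScalarMap      # negative tail
    config: PermutationConfig
    test: str                 # "one_sample" | "two_sample"
    n_effective_perms: int
    exhaustive: bool
    tail_approximated: bool = False

    def save(self, outdir, stem: str) -> dict:
        import json

        from .volumes import write_volume

        outdir = Path(outdir)
        paths = {}
        for name, smap in (
            ("stat", self.stat),
            ("p_fwe", self.p_fwe),
            ("p_fwe_pos", self.p_fwe_pos),
            ("p_fwe_neg", self.p_fwe_neg),
        ):
            paths[name] = write_volume(smap, outdir / f"{stem}_{name}.nii.gz").name
        sidecar = {
            "test": self.test,
            "n_permutations": self.config.n_permutations,
            "n_effective_perms": self.n_effective_perms,
            "seed": self.config.seed,
            "exhaustive": self.exhaustive,
            "tail_approximated": self.tail_approximated,
            "volumes": paths,
        }
        (outdir / f"{stem}_statmap.json").write_text(json.dumps(sidecar, indent=2))
        return sidecar


# ---------------------------------------------------------------------------
# One-sample sign-flip test


def _sign_matrix(n: int, config: PermutationConfig) -> tuple[np.ndarray, bool]:
    """All (exhaustive) or random sign assignments, one row per permutation."""
    if 2**n <= config.n_permutations:
        bits = np.arange(2**n, dtype=np.int64)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)) & 1)
        return signs.astype(float), True
    rng = np.random.default_rng(config.seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n))
    return signs, False


def _perm_t_from_signs(signs: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Sign-flip t statistics, (B, V). Uses the sign-invariance of sum(z^2)."""
    n, v = mat.shape
    mean = (signs @ mat) / n
    sumsq = (mat**2).sum(axis=0)
    var = np.maximum(sumsq - n * mean**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    deg = var == 0
    t[deg & (mean == 0)] = 0.0
    t[deg & (mean != 0)] = np.sign(mean[deg & (mean != 0)]) * T_CAP
    return t


def one_sample_permutation(z_maps, config: PermutationConfig | None = None) -> StatMap:
    """Sign-flip one-sample test over per-lesion maps with max-stat FWE."""
    config = config or PermutationConfig()
    if len(z_maps) < 2:
        raise VolumeError("one-sample test needs at least 2 lesion maps")
    mask = z_maps[0].defined_mask
    mat = np.stack([extract(m, mask) for m in z_maps])
    return one_sample_permutation_matrix(mat, mask, config)


def one_sample_permutation_matrix(
    mat: np.ndarray, mask: BinaryMask, config: PermutationConfig | None = None
) -> StatMap:
    """Fast path of :func:`one_sample_permutation` on an (n_lesions, V) matrix."""
    config = config or PermutationConfig()
    n = mat.shape[0]
    if n < 2:
        raise VolumeError("one-sample test needs at least 2 lesion maps")
    if np.ptp(mat) == 0 and mat.flat[0] != 0:
        raise VolumeError("all-constant nonzero input: sign-flip null is degenerate")
    # observed statistic through the same code path as the null, so the
    # identity assignment ties with the observation exactly
    t_obs = _perm_t_from_signs(np.ones((1, n)), mat)[0]
    signs, exhaustive = _sign_matrix(n, config)
    t_perm = _perm_t_from_signs(signs, mat)
    return _statmap_from_null(t_obs, t_perm, mask, config, "one_sample", exhaustive)


# ---------------------------------------------------------------------------
# Max-statistic FWE machinery


def _fwe_pvalues(
    obs: np.ndarray, null_max: np.ndarray, exhaustive: bool, config: PermutationConfig
) -> tuple[np.ndarray, bool]:
    """Corrected p per voxel against the max-over-voxels null distribution.

    Exhaustive enumerations (which include the identity assignment) give
    exact p = #{perm : max >= obs} / n_perm; Monte-Carlo runs use the
    Phipson–Smyth correction (1 + b) / (1 + B). Returns (p, used_gpd).
    """
    srt = np.sort(null_max)
    b = len(null_max) - np.searchsorted(srt, obs, side="left")
    if exhaustive:
        p = b / len(null_max)
        p = np.maximum(p, 1.0 / len(null_max))
        return p, False
    p = (1.0 + b) / (1.0 + len(null_max))
    used_gpd = False
    if config.tail_approximation:
        refine = p < config.gpd_trigger_p
        if np.any(refine):
            tail = fit_gpd_tail(null_max, config)
            if tail is not None:
                p_gpd = tail.sf(obs[refine])
                p[refine] = np.minimum(p[refine], np.maximum(p_gpd, np.finfo(float).eps))
                used_gpd = True
    return p, used_gpd


def _enforce_monotone(obs: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Within one map, a larger statistic never gets a larger p.

    Enforced conservatively (step-down style): walking down from the largest
    statistic, p-values may only be raised, never lowered.
    """
    order = np.argsort(-obs, kind="stable")
    q = np.maximum.accumulate(p[order])
    out = np.empty_like(p)
    out[order] = q
    return out


def _statmap_from_null(
    t_obs: np.ndarray,
    t_perm: np.ndarray,
    mask: BinaryMask,
    config: PermutationConfig,
    test: str,
    exhaustive: bool,
) -> StatMap:
    max_abs = np.abs(t_perm).max(axis=1)
    max_pos = t_perm.max(axis=1)
    min_neg = t_perm.min(axis=1)
    p_two, g1 = _fwe_pvalues(np.abs(t_obs), max_abs, exhaustive, config)
    p_pos, g2 = _fwe_pvalues(t_obs, max_pos, exhaustive, config)
    p_neg, g3 = _fwe_pvalues(-t_obs, -min_neg, exhaustive, config)
    p_two = _enforce_monotone(np.abs(t_obs), p_two)
    p_pos = _enforce_monotone(t_obs, p_pos)
    p_neg = _enforce_monotone(-t_obs, p_neg)
    return StatMap(
        stat=insert(t_obs, mask),
        p_fwe=insert(p_two, mask),
        p_fwe_pos=insert(p_pos, mask),
        p_fwe_neg=insert(p_neg, mask),
        config=config,
        test=test,
        n_effective_perms=t_perm.shape[0],
        exhaustive=exhaustive,
        tail_approximated=g1 or g2 or g3,
    )


def significant_mask(smap: StatMap, alpha: float | None = None, tail: str = "two_sided") -> BinaryMask:
    """Voxels with FWE-corrected p strictly below alpha, per tail."""
    alpha = alpha if alpha is not None else smap.config.fwe_alpha
    if not 0 < alpha <= 1:
        raise VolumeError("alpha must be in (0, 1]")
    pmap = {"two_sided": smap.p_fwe, "pos": smap.p_fwe_pos, "neg": smap.p_fwe_neg}[tail]
    if alpha == 1:  # "everything tested": p-values never exceed 1
        return BinaryMask(pmap.grid, pmap.defined_mask.data.copy())
    data = (pmap.data < alpha) & pmap.defined_mask.data
    return BinaryMask(pmap.grid, data)


# ---------------------------------------------------------------------------
# Generalized Pareto tail approximation


# Upper-tail critical values of the Anderson–Darling statistic for a GPD with
# both parameters estimated (Choulakian & Stephens 2001), indexed by their
# shape k (= -xi in the scipy parameterization).
_CS_K = np.array([0.9, 0.5, 0.2, 0.1, 0.0, -0.1, -0.2, -0.3, -0.4, -0.5])
_CS_A2 = {
    0.10: np.array([0.641, 0.685, 0.741, 0.766, 0.796, 0.831, 0.873, 0.924, 0.985, 1.061]),
    0.05: np.array([0.771, 0.830, 0.903, 0.935, 0.974, 1.020, 1.074, 1.140, 1.221, 1.321]),
    0.01: np.array([1.086, 1.180, 1.296, 1.348, 1.409, 1.481, 1.567, 1.672, 1.799, 1.958]),
}


def _ad_critical(c_shape: float, gof_alpha: float) -> float:
    col = min(_CS_A2, key=lambda a: abs(a - gof_alpha))
    k = float(np.clip(-c_shape, _CS_K.min(), _CS_K.max()))
    # _CS_K is decreasing; interpolate on the reversed axis
    return float(np.interp(k, _CS_K[::-1], _CS_A2[col][::-1]))


def _anderson_darling(exceedances: np.ndarray, c: float, scale: float) -> float:
    z = np.sort(stats.genpareto.cdf(exceedances, c, loc=0, scale=scale))
    z = np.clip(z, 1e-12, 1 - 1e-12)
    n = len(z)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1]))))


@dataclass
class FittedGPDTail:
    """A maximum-likelihood GPD fitted to the upper tail of a null sample."""

    threshold: float
    tail_fraction: float
    c: float
    scale: float
    n_exceedances: int

    def sf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        above = x > self.threshold
        out = np.full(x.shape, np.nan)
        out[above] = self.tail_fraction * stats.genpareto.sf(
            x[above] - self.threshold, self.c, loc=0, scale=self.scale
        )
        out[~above] = np.nan  # caller keeps the empirical p below threshold
        return np.where(np.isnan(out), 1.0, np.maximum(out, np.finfo(float).eps))


def fit_gpd_tail(
    null_samples: np.ndarray, config: PermutationConfig | None = None
) -> FittedGPDTail | None:
    """Fit a GPD to the upper tail, gated by an Anderson–Darling test.

    The threshold sits halfway between the k-th and (k+1)-th largest null
    values with k = floor(tail_fraction * n). If the fit fails the
    goodness-of-fit gate the tail is shrunk by 10 samples and refitted;
    returns None (caller falls back to the empirical p) when no acceptable
    fit exists or the tail is degenerate.
    """
    config = config or PermutationConfig()
    null = np.sort(np.asarray(null_samples, dtype=float))[::-1]
    n = len(null)
    k = int(np.floor(config.gpd_tail_fraction * n))
    while k >= 10:
        u = 0.5 * (null[k - 1] + null[k]) if k < n else null[k - 1] - 1e-12
        exc = null[:k] - u
        if np.ptp(exc) == 0:
            warnings.warn("degenerate permutation tail (all exceedances equal); "
                          "falling back to empirical p-values")
            return None
        try:
            c, _, scale = stats.genpareto.fit(exc, floc=0)
        except Exception:  # fit rarely fails to converge on pathological tails
            k -= 10
            continue
        a2 = _anderson_darling(exc, c, scale)
        if a2 < _ad_critical(c, config.gof_alpha):
            return FittedGPDTail(
                threshold=u, tail_fraction=k / n, c=float(c), scale=float(scale),
                n_exceedances=k,
            )
        k -= 10
    return None


def gpd_tail_pvalue(
    observed: float, null_samples, config: PermutationConfig | None = None
) -> float:
    """Tail-approximated permutation p for one observed statistic.

    Returns the empirical Phipson–Smyth p when it is at least
    ``gpd_trigger_p`` (or when no acceptable GPD fit exists); otherwise the
    fitted tail survival, floored at machine epsilon and never above the
    empirical p.
    """
    config = config or PermutationConfig()
    null = np.asarray(null_samples, dtype=float)
    if null.size == 0:
        raise VolumeError("null_samples must be nonempty")
    b = int(np.sum(null >= observed))
    p_emp = (1.0 + b) / (1.0 + null.size)
    if p_emp >= config.gpd_trigger_p or not config.tail_approximation:
        return float(p_emp)
    tail = fit_gpd_tail(null, config)
    if tail is None or observed <= tail.threshold:
        return float(p_emp)
    p = float(tail.sf(np.array([observed]))[0])
    return float(min(max(p, np.finfo(float).eps), p_emp, 1.0))


# ---------------------------------------------------------------------------
# Two-sample specificity test with syndrome blocks and equal syndrome weights


@dataclass
class GroupDesign:
    """Case-level design for the specificity contrast.

    ``group[i]`` is "sensory" or "comparison"; comparison cases carry a
    nonempty ``syndrome_label``. Weights give every comparison syndrome equal
    total weight (summing to the sensory group's total), so a large syndrome
    cannot dominate the contrast.
    """

    case_ids: list[str]
    group: list[str]
    syndrome_label: list[str]
    weights: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.case_ids)
        if not (len(self.group) == len(self.syndrome_label) == n):
            raise VolumeError("design fields have inconsistent lengths")
        for g, s in zip(self.group, self.syndrome_label):
            if g not in ("sensory", "comparison"):
                raise VolumeError(f"unknown group {g!r}")
            if g == "comparison" and not s:
                raise VolumeError("comparison cases need a syndrome_label")
        if self.weights is None:
            self.weights = self._equal_syndrome_weights()
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise VolumeError("weights must be positive")

    def _equal_syndrome_weights(self) -> np.ndarray:
        group = np.asarray(self.group)
        syn = np.asarray(self.syndrome_label)
        w = np.ones(len(group))
        n_sensory = int((group == "sensory").sum())
        syndromes = sorted(set(syn[group == "comparison"]))
        if syndromes:
            k = len(syndromes)
            for s in syndromes:
                members = (group == "comparison") & (syn == s)
                if members.sum() == 0:
                    raise VolumeError(f"syndrome {s!r} has zero cases")
                w[members] = n_sensory / (k * members.sum())
        return w


def _weighted_welch_t(x: np.ndarray, w: np.ndarray, in_g1: np.ndarray) -> np.ndarray:
    """Weighted Welch t per voxel. x: (n, V); w: (n,); in_g1: boolean (n,)."""
    def moments(sel):
        ws = w[sel]
        sw = ws.sum()
        sw2 = (ws**2).sum()
        m = (ws @ x[sel]) / sw
        dev2 = ws @ (x[sel] - m) ** 2
        denom = sw - sw2 / sw  # reliability-weight variance denominator
        s2 = dev2 / denom if denom > 0 else np.zeros_like(m)
        n_eff = sw**2 / sw2
        return m, s2 / n_eff
    m1, v1 = moments(in_g1)
    m2, v2 = moments(~in_g1)
    diff = m1 - m2
    se = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    deg = se == 0
    t[deg & (diff == 0)] = 0.0
    t[deg & (diff != 0)] = np.sign(diff[deg & (diff != 0)]) * T_CAP
    return t


def _blocks_from_design(design: GroupDesign) -> tuple[list[np.ndarray], int]:
    """Exchangeable units: each sensory case alone, each syndrome as one block."""
    group = np.asarray(design.group)
    syn = np.asarray(design.syndrome_label)
    blocks = [np.array([i]) for i in np.flatnonzero(group == "sensory")]
    n_g1_blocks = len(blocks)
    for s in sorted(set(syn[group == "comparison"])):
        blocks.append(np.flatnonzero((group == "comparison") & (syn == s)))
    return blocks, n_g1_blocks


def _weights_for_partition(n: int, blocks, g1_blocks: set) -> tuple[np.ndarray, np.ndarray]:
    """Recompute the equal-block weighting for a permuted block partition."""
    in_g1 = np.zeros(n, bool)
    w = np.ones(n)
    g2 = [b for i, b in enumerate(blocks) if i not in g1_blocks]
    n1 = 0
    for i in g1_blocks:
        in_g1[blocks[i]] = True
        n1 += len(blocks[i])
    k2 = len(g2)
    for b in g2:
        w[b] = n1 / (k2 * len(b))
    return w, in_g1


def two_sample_permutation(
    sensory_maps,
    comparison_maps,
    design: GroupDesign,
    config: PermutationConfig | None = None,
    block_permutation: bool = True,
) -> StatMap:
    """Weighted two-sample specificity test with block permutation and max-stat FWE."""
    config = config or PermutationConfig()
    if len(sensory_maps) < 2 or len(comparison_maps) < 2:
        raise VolumeError("each group needs at least 2 maps")
    mask = sensory_maps[0].defined_mask
    x = np.stack([extract(m, mask) for m in list(sensory_maps) + list(comparison_maps)])
    return two_sample_permutation_matrix(x, mask, design, config, block_permutation)


def two_sample_permutation_matrix(
    x: np.ndarray,
    mask: BinaryMask,
    design: GroupDesign,
    config: PermutationConfig | None = None,
    block_permutation: bool = True,
) -> StatMap:
    """Fast path on a stacked ((n1 + n2), V) matrix ordered as the design."""
    config = config or PermutationConfig()
    n = x.shape[0]
    if n != len(design.case_ids):
        raise VolumeError("matrix rows do not match design cases")
    group = np.asarray(design.group)
    in_g1_obs = group == "sensory"
    t_obs = _weighted_welch_t(x, design.weights, in_g1_obs)

    if block_permutation:
        blocks, n_g1_blocks = _blocks_from_design(design)
    else:
        blocks = [np.array([i]) for i in range(n)]
        n_g1_blocks = int(in_g1_obs.sum())
    rng = np.random.default_rng(config.seed)
    t_perm = np.empty((config.n_permutations, x.shape[1]))
    n_blocks = len(blocks)
    for b in range(config.n_permutations):
        chosen = set(rng.permutation(n_blocks)[:n_g1_blocks].tolist())
        w, in_g1 = _weights_for_partition(n, blocks, chosen)
        t_perm[b] = _weighted_welch_t(x, w, in_g1)
    return _statmap_from_null(t_obs, t_perm, mask, config, "two_sample", exhaustive=False)
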