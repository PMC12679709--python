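"""Synthetic normative connectomes and lesion cohorts with planted networks.

The generator emulates the statistical structure that lesion network mapping
relies on: spatially distant voxels that belong to one functional network
co-fluctuate across subjects. Each planted network owns a few disjoint
spherical "nodes"; within a subject every network draws an independent
standard-normal latent time course, and a voxel's signal is

    x_v(t) = a * L_k(t) + e_v(t),        e_v(t) ~ N(0, sigma^2) i.i.d.

for a voxel of network k with loading ``a`` (background voxels are pure
noise). Two voxels of the same network then have population correlation
r = a^2 / (a^2 + sigma^2) — the closed form every correlation test in this
package checks against — while voxels of different networks are independent.

Lesion cohorts are solid spheres placed either inside nodes of a chosen
target network ("hits", whose connectivity maps should light up the
network's remote nodes) or in background tissue, with patient metadata
(modality, direction) assigned from configurable per-group counts. A null
cohort (all loadings forced to zero) makes every downstream detection a
false positive, which is how the permutation machinery's error control is
audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .connectivity import Connectome
from .volumes import BinaryMask, ScalarMap, Series4D, VolumeError, VolumeGrid, write_volume

MODALITIES = ("auditory", "somatosensory")
DIRECTIONS = ("increase", "decrease")
COHORTS = ("sensory", "comparison", "hallucination")


@dataclass
class PlantedNetwork:
    name: str
    node_masks: list[BinaryMask]
    loading: float = 1.0

    def __post_init__(self) -> None:
        if self.loading <= 0:
            raise VolumeError(f"network {self.name}: loading must be > 0")
        union = np.zeros(self.node_masks[0].grid.shape, int)
        for m in self.node_masks:
            union += m.data
        if union.max() > 1:
            raise VolumeError(f"network {self.name}: node masks overlap")

    @property
    def union_mask(self) -> BinaryMask:
        data = np.zeros(self.node_masks[0].grid.shape, bool)
        for m in self.node_masks:
            data |= m.data
        return BinaryMask(self.node_masks[0].grid, data)


@dataclass
class LesionCase:
    case_id: str
    mask: BinaryMask
    modality: str
    direction: str
    cohort: str = "sensory"
    syndrome_label: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise VolumeError(f"unknown modality {self.modality!r}")
        if self.direction not in DIRECTIONS:
            raise VolumeError(f"unknown direction {self.direction!r}")
        if self.cohort not in COHORTS:
            raise VolumeError(f"unknown cohort {self.cohort!r}")
        if (self.cohort == "comparison") != bool(self.syndrome_label):
            raise VolumeError("syndrome_label must be set iff cohort == 'comparison'")
        self.mask.require_nonempty(f"lesion mask of {self.case_id}")


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic dataset; all randomness flows from ``seed``."""

    n_subjects: int = 20
    n_timepoints: int = 100
    grid: VolumeGrid | None = None
    networks: list[PlantedNetwork] | None = None
    noise_sd: float = 1.0
    n_lesions_per_group: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("auditory", "increase"): 0,  # the real cohort has this cell empty
            ("auditory", "decrease"): 2,
            ("somatosensory", "increase"): 2,
            ("somatosensory", "decrease"): 2,
        }
    )
    lesion_radius: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise VolumeError("need at least 2 subjects")
        if self.n_timepoints < 10:
            raise VolumeError("need at least 10 timepoints")
        if self.noise_sd <= 0:
            raise VolumeError("noise_sd must be positive")
        if any(v < 0 for v in self.n_lesions_per_group.values()):
            raise VolumeError("group counts must be >= 0")
        if self.grid is None:
            self.grid = default_grid()
        if self.networks is None:
            self.networks = default_networks(self.grid)

    @property
    def n_lesions(self) -> int:
        return sum(self.n_lesions_per_group.values())

    def brain_mask(self) -> BinaryMask:
        data = _sphere(self.grid, _center(self.grid), radius=min(self.grid.shape) / 2 - 1.5)
        for net in self.networks:
            data |= net.union_mask.data
        return BinaryMask(self.grid, data)

    def network(self, name: str) -> PlantedNetwork:
        for net in self.networks:
            if net.name == name:
                return net
        raise VolumeError(f"no planted network named {name!r}")


# ---------------------------------------------------------------------------
# Default desk-scale geometry: 24^3 grid, 3 networks x 3 spherical nodes


def default_grid(n: int = 24) -> VolumeGrid:
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -float(n - 1)  # voxel centers span [-(n-1), n-1] mm
    return VolumeGrid((n, n, n), affine, space_label="synthetic-grid")

_NODE_CENTERS = [
    (6, 6, 6), (6, 6, 17), (6, 17, 6),
    (17, 6, 6), (17, 17, 6), (17, 6, 17),
    (6, 17, 17), (17, 17, 17), (11, 11, 11),
]


def default_networks(grid: VolumeGrid, loading: float = 1.0, node_radius: float = 2.0):
    """Three networks of three well-separated spherical nodes each."""
    nets = []
    scale = grid.shape[0] / 24.0
    for k in range(3):
        nodes = []
        for cx, cy, cz in _NODE_CENTERS[3 * k : 3 * k + 3]:
            center = np.array([cx, cy, cz]) * scale
            nodes.append(BinaryMask(grid, _sphere(grid, center, node_radius * scale)))
        nets.append(PlantedNetwork(name=f"net{k}", node_masks=nodes, loading=loading))
    return nets


def _center(grid: VolumeGrid) -> np.ndarray:
    return (np.asarray(grid.shape) - 1) / 2.0


def _sphere(grid: VolumeGrid, center, radius: float) -> np.ndarray:
    idx = np.indices(grid.shape)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius**2


# ---------------------------------------------------------------------------
# Generation


def generate_connectome(spec: SyntheticCohortSpec) -> Connectome:
    """Planted-network connectome; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    mask = spec.brain_mask()
    v = mask.n_true
    # network id per in-mask column (-1 = background)
    net_of_col = np.full(v, -1)
    loadings = np.zeros(len(spec.networks))
    for k, net in enumerate(spec.networks):
        inside = net.union_mask.data[mask.data]
        if np.any(net_of_col[inside] >= 0):
            raise VolumeError("planted networks overlap")
        net_of_col[inside] = k
        loadings[k] = net.loading
    series = []
    t = spec.n_timepoints
    for _ in range(spec.n_subjects):
        latents = rng.standard_normal((t, len(spec.networks)))
        x = rng.normal(0.0, spec.noise_sd, size=(t, v))
        for k in range(len(spec.networks)):
            cols = net_of_col == k
            if cols.any():
                x[:, cols] += loadings[k] * latents[:, [k]]
        series.append(x)
    return Connectome(series, mask)


def sample_lesion_cohort(
    spec: SyntheticCohortSpec,
    target_network: str,
    hit_fraction: float = 1.0,
    cohort: str = "sensory",
    syndrome_label: str = "",
    id_prefix: str = "case",
    rng: np.random.Generator | None = None,
) -> list[LesionCase]:
    """Lesion cohort in which ``hit_fraction`` of masks intersect the target network.

    Hits are spheres centered (with small jitter) inside randomly chosen nodes
    of the target network; the rest land in background tissue away from every
    planted node. Metadata follows ``spec.n_lesions_per_group``.
    """
    if not 0.0 <= hit_fraction <= 1.0:
        raise VolumeError("hit_fraction must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    target = spec.network(target_network)
    brain = spec.brain_mask()
    all_nodes = np.zeros(spec.grid.shape, bool)
    for net in spec.networks:
        all_nodes |= net.union_mask.data

    groups: list[tuple[str, str]] = []
    for (modality, direction), count in sorted(spec.n_lesions_per_group.items()):
        groups.extend([(modality, direction)] * count)
    n = len(groups)
    n_hit = int(round(hit_fraction * n))
    hit_flags = np.zeros(n, bool)
    hit_flags[rng.permutation(n)[:n_hit]] = True

    cases = []
    for i, ((modality, direction), hit) in enumerate(zip(groups, hit_flags)):
        if hit:
            data = _place_hit(spec, target, rng)
        else:
            data = _place_background(spec, brain, all_nodes, rng)
        cases.append(
            LesionCase(
                case_id=f"{id_prefix}_{i:03d}",
                mask=BinaryMask(spec.grid, data),
                modality=modality,
                direction=direction,
                cohort=cohort,
                syndrome_label=syndrome_label,
            )
        )
    return cases


def _place_hit(spec, network: PlantedNetwork, rng) -> np.ndarray:
    for _ in range(1000):
        node = network.node_masks[rng.integers(len(network.node_masks))]
        true_idx = np.argwhere(node.data)
        center = true_idx.mean(axis=0) + rng.integers(-1, 2, size=3)
        data = _sphere(spec.grid, center, spec.lesion_radius)
        if (data & node.data).any():
            return data
    raise VolumeError("could not place a lesion intersecting the target network")


def _place_background(spec, brain: BinaryMask, all_nodes: np.ndarray, rng) -> np.ndarray:
    candidates = np.argwhere(brain.data & ~all_nodes)
    for _ in range(1000):
        center = candidates[rng.integers(len(candidates))]
        data = _sphere(spec.grid, center, spec.lesion_radius)
        if (data & brain.data).any() and not (data & all_nodes).any():
            return data
    raise VolumeError("could not place a background lesion avoiding all networks")


def sample_comparison_cohorts(
    spec: SyntheticCohortSpec,
    syndrome_sizes: dict[str, int],
    rng: np.random.Generator | None = None,
) -> list[LesionCase]:
    """Multi-syndrome comparison library: background lesions grouped by syndrome."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    brain = spec.brain_mask()
    all_nodes = np.zeros(spec.grid.shape, bool)
    for net in spec.networks:
        all_nodes |= net.union_mask.data
    cases = []
    for syndrome, size in sorted(syndrome_sizes.items()):
        if size < 1:
            raise VolumeError(f"syndrome {syndrome!r} has zero cases")
        for i in range(size):
            data = _place_background(spec, brain, all_nodes, rng)
            cases.append(
                LesionCase(
                    case_id=f"{syndrome}_{i:03d}",
                    mask=BinaryMask(spec.grid, data),
                    modality=MODALITIES[int(rng.integers(2))],
                    direction=DIRECTIONS[int(rng.integers(2))],
                    cohort="comparison",
                    syndrome_label=syndrome,
                )
            )
    return cases


def generate_null_cohort(
    spec: SyntheticCohortSpec, hit_fraction: float = 0.5
) -> tuple[Connectome, list[LesionCase]]:
    """Pure-noise connectome plus an arbitrary lesion cohort.

    Every loading is forced to zero, so any downstream detection is a false
    positive: this is the harness for auditing familywise error control.
    """
    rng = np.random.default_rng(spec.seed)
    mask = spec.brain_mask()
    series = [
        rng.normal(0.0, spec.noise_sd, size=(spec.n_timepoints, mask.n_true))
        for _ in range(spec.n_subjects)
    ]
    connectome = Connectome(series, mask)
    cases = sample_lesion_cohort(
        spec,
        target_network=spec.networks[0].name,
        hit_fraction=hit_fraction,
        rng=np.random.default_rng(spec.seed + 1),
    )
    return connectome, cases


# ---------------------------------------------------------------------------
# On-disk datasets (per-subject 4D NIfTI + masks + cohort CSV + YAML spec)


def write_dataset(spec: SyntheticCohortSpec, outdir, target_network: str = "net0",
                  hit_fraction: float = 1.0) -> dict:
    """Materialize a dataset on disk; returns a manifest of written paths."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    connectome = generate_connectome(spec)
    cases = sample_lesion_cohort(spec, target_network, hit_fraction)
    mask = connectome.brain_mask
    write_volume(mask, outdir / "brain_mask.nii.gz")
    subject_paths = []
    for s, mat in enumerate(connectome.series):
        vol = np.zeros(spec.grid.shape + (spec.n_timepoints,))
        vol[mask.data] = mat.T
        p = write_volume(Series4D(spec.grid, vol), outdir / f"subject_{s:03d}.nii.gz")
        subject_paths.append(str(p))
    rows = []
    for case in cases:
        mp = write_volume(case.mask, outdir / "lesions" / f"{case.case_id}.nii.gz")
        rows.append(
            {
                "case_id": case.case_id,
                "mask_path": str(mp),
                "modality": case.modality,
                "direction": case.direction,
                "cohort": case.cohort,
                "syndrome_label": case.syndrome_label,
            }
        )
    cohort_csv = outdir / "cohort.csv"
    pd.DataFrame(rows).to_csv(cohort_csv, index=False)
    spec_path = outdir / "spec.yaml"
    spec_path.write_text(spec_to_yaml(spec))
    return {
        "brain_mask": str(outdir / "brain_mask.nii.gz"),
        "subjects": subject_paths,
        "cohort_table": str(cohort_csv),
        "spec": str(spec_path),
    }


def spec_to_yaml(spec: SyntheticCohortSpec) -> str:
    payload = {
        "n_subjects": spec.n_subjects,
        "n_timepoints": spec.n_timepoints,
        "grid_size": spec.grid.shape[0],
        "n_networks": len(spec.networks),
        "loading": spec.networks[0].loading if spec.networks else 1.0,
        "noise_sd": spec.noise_sd,
        "lesion_radius": spec.lesion_radius,
        "seed": spec.seed,
        "n_lesions_per_group": {
            f"{m}:{d}": c for (m, d), c in sorted(spec.n_lesions_per_group.items())
        },
    }
    return yaml.safe_dump(payload, sort_keys=False)


def spec_from_yaml(text: str) -> SyntheticCohortSpec:
    payload = yaml.safe_load(text)
    grid = default_grid(payload.get("grid_size", 24))
    networks = default_networks(grid, loading=payload.get("loading", 1.0))[
        : payload.get("n_networks", 3)
    ]
    groups = {
        tuple(k.split(":")): v for k, v in payload.get("n_lesions_per_group", {}).items()
    }
    kwargs = dict(
        n_subjects=payload["n_subjects"],
        n_timepoints=payload["n_timepoints"],
        grid=grid,
        networks=networks,
        noise_sd=payload.get("noise_sd", 1.0),
        lesion_radius=payload.get("lesion_radius", 1.6),
        seed=payload.get("seed", 0),
    )
    if groups:
        kwargs["n_lesions_per_group"] = groups
    return SyntheticCohortSpec(**kwargs)
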