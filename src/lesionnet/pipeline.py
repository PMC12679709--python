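"""End-to-end orchestration: connectivity -> overlap -> inference -> reports.

One :class:`RunConfig` drives the whole analysis for a cohort table:
per-lesion connectivity maps, the thresholded overlap map and its peak
report, one-sample sensitivity and two-sample specificity permutation tests,
their conjunction, optional cross-cohort conjunction against a second
(hallucination) cohort, atlas coverage, and subgroup reruns split by symptom
direction and modality. Every stage derives its own seed from the single run
seed so stages are individually reproducible, and a JSON manifest records
configuration, seeds, and every output path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import Connectome, ConnectivityMap, connectivity_maps
from .overlap import overlap_from_cmaps, overlap_peak_report, required_count
from .parcellation import AtlasParcellation, conjunction, coverage, region_table
from .permutation import (
    GroupDesign,
    PermutationConfig,
    StatMap,
    one_sample_permutation_matrix,
    significant_mask,
    two_sample_permutation_matrix,
)
from .synthetic import DIRECTIONS, MODALITIES, LesionCase
from .volumes import BinaryMask, VolumeError, extract, read_mask, write_volume

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["case_id", "mask_path", "modality", "direction", "cohort", "syndrome_label"]

DEFAULT_SUBGROUPS: dict[str, dict[str, str]] = {
    "increase": {"direction": "increase"},
    "decrease": {"direction": "decrease"},
    "auditory": {"modality": "auditory"},
    "somatosensory": {"modality": "somatosensory"},
    "auditory_increase": {"modality": "auditory", "direction": "increase"},
    "auditory_decrease": {"modality": "auditory", "direction": "decrease"},
    "somatosensory_increase": {"modality": "somatosensory", "direction": "increase"},
    "somatosensory_decrease": {"modality": "somatosensory", "direction": "decrease"},
}


@dataclass
class RunConfig:
    subject_paths: list[str]
    brain_mask_path: str
    cohort_table: str
    output_dir: str
    comparison_table: str | None = None
    hallucination_table: str | None = None
    atlas_label_path: str | None = None
    atlas_names_path: str | None = None
    overlap_theta: float = 7.0
    overlap_fraction: float = 0.9
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    subgroups: dict[str, dict[str, str]] = field(default_factory=lambda: dict(DEFAULT_SUBGROUPS))
    region_points: list[tuple] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overlap_theta <= 0:
            raise VolumeError("overlap_theta must be positive")
        for name, flt in self.subgroups.items():
            bad = set(flt) - {"modality", "direction", "cohort", "syndrome_label"}
            if bad:
                raise VolumeError(f"subgroup {name!r} filters unknown fields {sorted(bad)}")


def load_run_config(path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    perm = PermutationConfig(**payload.pop("permutation", {}))
    return RunConfig(permutation=perm, **payload)


def derive_seed(seed: int, stage: str) -> int:
    digest = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def validate_cohort(table_path, expected_cohort: str | None = None) -> list[LesionCase]:
    """Read and type-check a cohort CSV; loads and checks every lesion mask."""
    table_path = Path(table_path)
    df = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VolumeError(f"cohort table {table_path} missing columns: {missing}")
    dup = df["case_id"][df["case_id"].duplicated()]
    if not dup.empty:
        raise VolumeError(f"duplicate case_id in {table_path}: {dup.iloc[0]!r}")
    cases = []
    for row in df.itertuples(index=False):
        mask_path = Path(row.mask_path)
        if not mask_path.is_absolute():
            mask_path = table_path.parent / mask_path
        mask = read_mask(mask_path)
        if expected_cohort and row.cohort != expected_cohort:
            raise VolumeError(
                f"case {row.case_id}: cohort {row.cohort!r}, expected {expected_cohort!r}"
            )
        cases.append(
            LesionCase(
                case_id=row.case_id,
                mask=mask,
                modality=row.modality,
                direction=row.direction,
                cohort=row.cohort,
                syndrome_label=row.syndrome_label,
            )
        )
    return cases


def filter_cases(cases: list[LesionCase], flt: dict[str, str]) -> list[LesionCase]:
    return [c for c in cases if all(getattr(c, k) == v for k, v in flt.items())]


# ---------------------------------------------------------------------------


def _z_matrix(cmaps: dict[str, ConnectivityMap], mask: BinaryMask) -> np.ndarray:
    return np.stack([extract(cmaps[i].mean_z, mask) for i in sorted(cmaps)])


def _analyse_cohort(
    name: str,
    cases: list[LesionCase],
    cmaps: dict[str, ConnectivityMap],
    comparison_cases: list[LesionCase] | None,
    comparison_cmaps: dict[str, ConnectivityMap] | None,
    connectome: Connectome,
    config: RunConfig,
    outdir: Path,
    manifest: dict,
) -> None:
    mask = connectome.brain_mask
    stage_dir = outdir / name
    stage_dir.mkdir(parents=True, exist_ok=True)
    entry: dict = {"n_lesions": len(cases), "outputs": {}}
    manifest["cohorts"][name] = entry
    ids = [c.case_id for c in cases]
    sub_cmaps = {i: cmaps[i] for i in ids}

    # overlap map + peak report
    omap = overlap_from_cmaps(list(sub_cmaps.values()), config.overlap_theta)
    from .volumes import ScalarMap

    for tail, counts in (("pos", omap.counts_pos), ("neg", omap.counts_neg)):
        p = write_volume(ScalarMap(mask.grid, counts.astype(float)), stage_dir / f"overlap_{tail}.nii.gz")
        entry["outputs"][f"overlap_{tail}"] = str(p)
    peaks = overlap_peak_report(omap, config.overlap_fraction)
    peaks_path = stage_dir / "overlap_peaks.csv"
    peaks.to_csv(peaks_path, index=False)
    entry["outputs"]["overlap_peaks"] = str(peaks_path)
    entry["overlap_required_count"] = required_count(config.overlap_fraction, len(cases))

    # one-sample sensitivity test
    perm_cfg = PermutationConfig(
        **{**asdict(config.permutation), "seed": derive_seed(config.seed, f"one_sample:{name}")}
    )
    z_mat = _z_matrix(sub_cmaps, mask)
    smap = one_sample_permutation_matrix(z_mat, mask, perm_cfg)
    entry["outputs"]["one_sample"] = smap.save(stage_dir, "one_sample")
    sig_pos = significant_mask(smap, tail="pos")
    sig_neg = significant_mask(smap, tail="neg")
    entry["n_significant_pos"] = sig_pos.n_true
    entry["n_significant_neg"] = sig_neg.n_true

    # two-sample specificity test + conjunction
    if comparison_cases:
        comp_ids = [c.case_id for c in comparison_cases]
        design = GroupDesign(
            case_ids=ids + comp_ids,
            group=["sensory"] * len(ids) + ["comparison"] * len(comp_ids),
            syndrome_label=[""] * len(ids) + [c.syndrome_label for c in comparison_cases],
        )
        comp_mat = np.stack([extract(comparison_cmaps[i].mean_z, mask) for i in comp_ids])
        perm_cfg2 = PermutationConfig(
            **{**asdict(config.permutation), "seed": derive_seed(config.seed, f"two_sample:{name}")}
        )
        x = np.vstack([z_mat, comp_mat])
        smap2 = two_sample_permutation_matrix(x, mask, design, perm_cfg2)
        entry["outputs"]["two_sample"] = smap2.save(stage_dir, "two_sample")
        for tail, sig in (("pos", sig_pos), ("neg", sig_neg)):
            conj = conjunction([sig, significant_mask(smap2, tail=tail)])
            p = write_volume(conj, stage_dir / f"conjunction_sensitive_specific_{tail}.nii.gz")
            entry["outputs"][f"conjunction_{tail}"] = str(p)
            entry[f"n_conjunction_{tail}"] = conj.n_true

    # atlas coverage
    if config.atlas_label_path:
        atlas = AtlasParcellation.from_files(config.atlas_label_path, config.atlas_names_path)
        atlas = atlas.to_grid(mask.grid)
        cov = coverage(sig_pos, atlas)
        cov_path = stage_dir / "coverage_pos.csv"
        cov.to_csv(cov_path, index=False)
        entry["outputs"]["coverage_pos"] = str(cov_path)

    # region table at named coordinates
    if config.region_points:
        table = region_table(sig_pos, smap.stat, config.region_points)
        rt_path = stage_dir / "region_table.csv"
        table.to_csv(rt_path, index=False)
        entry["outputs"]["region_table"] = str(rt_path)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the complete analysis; returns (and writes) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "overlap_theta": config.overlap_theta,
        "overlap_fraction": config.overlap_fraction,
        "n_permutations": config.permutation.n_permutations,
        "cohorts": {},
        "skipped_subgroups": [],
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in asdict(config).items()}, sort_keys=True, default=str
            ).encode()
        ).hexdigest()[:16],
    }

    connectome = Connectome.from_files(config.subject_paths, config.brain_mask_path)
    cases = validate_cohort(config.cohort_table)
    logger.info("validated %d sensory cases", len(cases))
    cmaps = connectivity_maps(connectome, {c.case_id: c.mask for c in cases})

    comparison_cases = comparison_cmaps = None
    if config.comparison_table:
        comparison_cases = validate_cohort(config.comparison_table, expected_cohort="comparison")
        comparison_cmaps = connectivity_maps(
            connectome, {c.case_id: c.mask for c in comparison_cases}
        )

    groups: dict[str, list[LesionCase]] = {"full_cohort": cases}
    for name, flt in config.subgroups.items():
        groups[name] = filter_cases(cases, flt)

    for name, members in groups.items():
        if len(members) < 2:
            logger.info("subgroup %r has %d case(s); skipped", name, len(members))
            manifest["skipped_subgroups"].append(name)
            continue
        _analyse_cohort(
            name, members, cmaps, comparison_cases, comparison_cmaps,
            connectome, config, outdir, manifest,
        )

    if config.hallucination_table:
        _cross_cohort_conjunction(config, connectome, cases, cmaps, outdir, manifest)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _one_sample_statmap(name, members, cmaps, mask, config) -> StatMap:
    perm_cfg = PermutationConfig(
        **{**asdict(config.permutation), "seed": derive_seed(config.seed, f"one_sample:{name}")}
    )
    mat = np.stack([extract(cmaps[c.case_id].mean_z, mask) for c in members])
    return one_sample_permutation_matrix(mat, mask, perm_cfg)


def _cross_cohort_conjunction(config, connectome, cases, cmaps, outdir, manifest) -> None:
    """Conjunction of the sensory and hallucination one-sample maps.

    Both cohorts' maps are binarized at the same FWE alpha; a second,
    modality-restricted variant conjoins only the auditory cases of each.
    """
    hal_cases = validate_cohort(config.hallucination_table)
    hal_cmaps = connectivity_maps(connectome, {c.case_id: c.mask for c in hal_cases})
    mask = connectome.brain_mask
    stage_dir = outdir / "cross_cohort"
    stage_dir.mkdir(parents=True, exist_ok=True)
    entry: dict = {"outputs": {}}
    manifest["cohorts"]["cross_cohort"] = entry

    pairs = {"all": (cases, hal_cases)}
    aud_sens = filter_cases(cases, {"modality": "auditory"})
    aud_hal = filter_cases(hal_cases, {"modality": "auditory"})
    if len(aud_sens) >= 2 and len(aud_hal) >= 2:
        pairs["auditory"] = (aud_sens, aud_hal)
    else:
        manifest["skipped_subgroups"].append("cross_cohort_auditory")

    for variant, (sens, hal) in pairs.items():
        sm_sens = _one_sample_statmap(f"cross_sens_{variant}", sens, cmaps, mask, config)
        sm_hal = _one_sample_statmap(f"cross_hal_{variant}", hal, hal_cmaps, mask, config)
        for tail in ("pos", "neg"):
            conj = conjunction(
                [significant_mask(sm_sens, tail=tail), significant_mask(sm_hal, tail=tail)]
            )
            p = write_volume(conj, stage_dir / f"conjunction_{variant}_{tail}.nii.gz")
            entry["outputs"][f"conjunction_{variant}_{tail}"] = str(p)
            entry[f"n_conjunction_{variant}_{tail}"] = conj.n_true
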