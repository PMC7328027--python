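"""End-to-end pipelines tying the stages together, plus configuration.

Two analyses are orchestrated here: the whole-brain mean-centered task PLS
(:func:`run_task_pls`) and the seed-PLS connectivity analysis
(:func:`run_seed_pls`).  Both consume a validated configuration mapping,
run activity reduction -> decomposition -> resampling -> peak reporting,
and are deterministic given the configured seed.

Data can come from the synthetic generator (default) or from a real-data
path: one 4-D NIfTI per subject plus a block-timing table (TSV with
columns run, onset_s, duration_s, condition) and a mask NIfTI defining the
voxel order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavioral as beh
from .activity import BlockSeries, SubjectActivity, average_condition_activity, exclude_conditions
from .design import ANALYSIS_CONDITIONS, CONDITIONS, GROUPS, generate_design
from .pls import MeanCenteredPLS, TaskPLSResults
from .seed import DEFAULT_SEEDS_MM, SeedPLS, SeedPLSResults, SeedSpec
from .simulate import simulate_dataset
from .space import VoxelSpace, default_space, find_peaks, read_mask

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "load_config",
    "validate_config",
    "default_config",
    "run_task_pls",
    "run_seed_pls",
    "run_behavioral",
    "blocks_from_nifti",
    "write_synthetic_dataset",
]


class ConfigError(ValueError):
    """Configuration/schema violation, naming the offending field."""


# field -> (type, validator or None)
_SCHEMA = {
    "seed": (int, lambda v: v >= 0),
    "out_dir": (str, None),
    "mask_shape": (list, lambda v: len(v) == 3 and all(int(x) > 0 for x in v)),
    "noise_sd": ((int, float), lambda v: v >= 0),
    "design": (dict, None),
    "exclude_conditions": (list, None),
    "n_permutations": (int, lambda v: v >= 0),
    "n_bootstrap": (int, lambda v: v >= 0),
    "bsr_threshold": ((int, float), lambda v: v > 0),
    "min_peak_separation_mm": ((int, float), lambda v: v >= 0),
    "alignment": (str, lambda v: v in ("procrustes", "signs", "none")),
    "centering": (str, lambda v: v in ("grand", "group")),
    "seeds": ((dict, str), None),
    "data": (dict, None),
}

_DESIGN_SCHEMA = {
    "n_runs": (int, lambda v: v >= 1),
    "blocks_per_run": (int, lambda v: v >= 1),
    "trials_per_block": (int, lambda v: v >= 1),
    "conditions": (list, lambda v: len(v) >= 1),
}


def default_config() -> dict:
    """The synthetic default analysis configuration."""
    return {
        "seed": 0,
        "out_dir": "socialpls_out",
        "mask_shape": [12, 12, 12],
        "noise_sd": 1.0,
        "design": {"n_runs": 5, "blocks_per_run": 14, "trials_per_block": 5,
                   "conditions": list(CONDITIONS)},
        "exclude_conditions": ["famous"],
        "n_permutations": 500,
        "n_bootstrap": 100,
        "bsr_threshold": 2.58,
        "min_peak_separation_mm": 10.0,
        "alignment": "procrustes",
        "centering": "grand",
        "seeds": "default",
        "data": {"kind": "synthetic"},
    }


def validate_config(config: dict) -> dict:
    """Merge with defaults and validate; raises ConfigError naming fields."""
    merged = default_config()
    for key, value in (config or {}).items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown configuration field {key!r}")
        typ, check = _SCHEMA[key]
        if not isinstance(value, typ) or isinstance(value, bool):
            raise ConfigError(
                f"field {key!r}: expected {typ}, got {type(value).__name__}"
            )
        if check is not None and not check(value):
            raise ConfigError(f"field {key!r}: invalid value {value!r}")
        if key == "design":
            sub = dict(merged["design"])
            for dk, dv in value.items():
                if dk not in _DESIGN_SCHEMA:
                    raise ConfigError(f"unknown configuration field 'design.{dk}'")
                dtyp, dcheck = _DESIGN_SCHEMA[dk]
                if not isinstance(dv, dtyp) or isinstance(dv, bool):
                    raise ConfigError(
                        f"field 'design.{dk}': expected {dtyp}, "
                        f"got {type(dv).__name__}"
                    )
                if dcheck is not None and not dcheck(dv):
                    raise ConfigError(f"field 'design.{dk}': invalid value {dv!r}")
                sub[dk] = dv
            merged["design"] = sub
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path | None) -> dict:
    """Load and validate a YAML configuration file (None -> defaults)."""
    if path is None:
        return validate_config({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return validate_config(raw)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _prepare(config: dict):
    """Materialize space + analysis-ready subjects from a validated config."""
    cfg = validate_config(config)
    data = cfg["data"]
    kind = data.get("kind", "synthetic")
    if kind == "synthetic":
        space = default_space(tuple(cfg["mask_shape"]))
        d = cfg["design"]
        design = generate_design(
            d["n_runs"], d["blocks_per_run"], d["trials_per_block"],
            tuple(d["conditions"]), GROUPS, rng=cfg["seed"],
        )
        ds = simulate_dataset(
            design=design,
            mask_shape=tuple(cfg["mask_shape"]),
            noise_sd=float(cfg["noise_sd"]),
            seed=cfg["seed"],
            behavioral=False,
        )
        subjects = list(ds.subjects)
    elif kind == "nifti":
        for field in ("mask", "subjects", "tr_s"):
            if field not in data:
                raise ConfigError(f"field 'data.{field}' is required for kind=nifti")
        space = read_mask(data["mask"])
        subjects = []
        for rec in data["subjects"]:
            timing = pd.read_csv(rec["timing"], sep="\t")
            blocks = blocks_from_nifti(
                rec["bold"], space, timing, float(data["tr_s"]),
                subject_id=rec["id"],
                inter_block_fixation_s=float(data.get("inter_block_fixation_s", 10.0)),
            )
            kept = tuple(
                c for c in timing["condition"].unique()
                if c not in cfg["exclude_conditions"]
            )
            subjects.append(
                average_condition_activity(blocks, kept, group=rec["group"])
            )
    else:
        raise ConfigError(f"field 'data.kind': unknown kind {kind!r}")
    drop = tuple(c for c in cfg["exclude_conditions"] if c in subjects[0].conditions)
    if drop:
        subjects = exclude_conditions(subjects, drop)
    logger.info(
        "prepared %d subjects, %d voxels, conditions %s (config %s, seed %d)",
        len(subjects), subjects[0].n_voxels, subjects[0].conditions,
        _config_hash(cfg), cfg["seed"],
    )
    return cfg, space, subjects


def run_task_pls(
    config: dict | None = None, out_dir: str | Path | None = None
) -> tuple[TaskPLSResults, pd.DataFrame]:
    """Whole-brain mean-centered task PLS: fit, report peaks, serialize."""
    cfg, space, subjects = _prepare(config or {})
    model = MeanCenteredPLS(subjects, center=cfg["centering"])
    rng = np.random.default_rng(cfg["seed"] + 1)
    results = model.fit(
        n_perm=cfg["n_permutations"],
        n_boot=cfg["n_bootstrap"],
        rng=rng,
        align=cfg["alignment"],
    )
    peaks = _peak_table(results.bootstrap_ratios, space, cfg)
    out = Path(out_dir) if out_dir is not None else Path(cfg["out_dir"]) / "taskpls"
    results.save(out, space=space)
    peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    space.write_mask(out / "mask.nii.gz")
    return results, peaks


def run_seed_pls(
    config: dict | None = None,
    seed_name: str = "dmpfc",
    out_dir: str | Path | None = None,
) -> tuple[SeedPLSResults, pd.DataFrame]:
    """Seed-PLS connectivity for one named seed region."""
    cfg, space, subjects = _prepare(config or {})
    seeds = cfg["seeds"]
    if seeds == "default":
        seeds = {name: {"mm": list(mm)} for name, mm in DEFAULT_SEEDS_MM.items()}
    if seed_name not in seeds:
        raise ConfigError(
            f"unknown seed {seed_name!r}; available: {sorted(seeds)}"
        )
    spec = seeds[seed_name]
    seed = SeedSpec.from_peak(
        space,
        ijk=tuple(spec["ijk"]) if "ijk" in spec else None,
        mm=tuple(spec["mm"]) if "mm" in spec else None,
        name=seed_name,
    )
    model = SeedPLS(subjects, seed)
    rng = np.random.default_rng(cfg["seed"] + 2)
    results = model.fit(
        n_perm=cfg["n_permutations"],
        n_boot=cfg["n_bootstrap"],
        rng=rng,
        align=cfg["alignment"],
    )
    peaks = _peak_table(results.bootstrap_ratios, space, cfg)
    out = (
        Path(out_dir)
        if out_dir is not None
        else Path(cfg["out_dir"]) / f"seedpls_{seed_name}"
    )
    results.save(out, space=space)
    peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    return results, peaks


def _peak_table(bsr: np.ndarray | None, space: VoxelSpace, cfg: dict) -> pd.DataFrame:
    if bsr is None:
        return pd.DataFrame(columns=["x_mm", "y_mm", "z_mm", "bsr", "sign", "lv"])
    clean = np.where(np.isfinite(bsr), bsr, 0.0)
    return find_peaks(
        clean,
        space,
        threshold=float(cfg["bsr_threshold"]),
        min_separation_mm=float(cfg["min_peak_separation_mm"]),
    )


def run_behavioral(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summaries plus the recomputable group tests from a behavioral table.

    Returns a summary table (group x condition x measure), young-vs-older
    pooled t/F tests per condition and measure, and per-group Friedman
    tests over partner / parent-child / friend.
    """
    summary = beh.summarize_by_condition(table)
    tests = []
    for measure in summary["measure"].unique():
        for cond in summary["condition"].unique():
            cell = summary[(summary.measure == measure) & (summary.condition == cond)]
            if set(cell["group"]) != {"young", "older"}:
                continue
            a = cell[cell.group == "young"].iloc[0]
            b = cell[cell.group == "older"].iloc[0]
            if a["n"] < 2 or b["n"] < 2 or (a["sd"] == 0 and b["sd"] == 0 and a["mean"] != b["mean"]):
                continue
            res = beh.pooled_two_sample_from_summary(
                (a["n"], a["mean"], a["sd"]), (b["n"], b["mean"], b["sd"])
            )
            tests.append(
                {
                    "measure": measure,
                    "condition": cond,
                    "t": res.t,
                    "F": res.F,
                    "df": res.df[1],
                    "p": res.p,
                }
            )
    friedman = []
    close = ["partner", "parent_child", "friend"]
    for measure in ("whoto_total", "ios"):
        if measure not in table.columns:
            continue
        for group in table["group"].unique():
            wide = (
                table[table.group == group]
                .pivot(index="subject_id", columns="condition", values=measure)
            )
            if not set(close) <= set(wide.columns):
                continue
            res = beh.friedman_test(wide[close].to_numpy())
            friedman.append(
                {
                    "measure": measure,
                    "group": group,
                    "chi2": res.chi2,
                    "df": res.df,
                    "n": wide.shape[0],
                    "p": res.p,
                }
            )
    return {
        "summary": summary,
        "group_tests": pd.DataFrame(tests),
        "friedman": pd.DataFrame(friedman),
    }


def blocks_from_nifti(
    bold_path: str | Path,
    space: VoxelSpace,
    timing: pd.DataFrame,
    tr_s: float,
    subject_id: str = "sub",
    inter_block_fixation_s: float = 10.0,
) -> list[BlockSeries]:
    """Block means + preceding-fixation means from a 4-D NIfTI time series.

    ``timing`` columns: run, onset_s, duration_s, condition (onsets within
    run, one row per block).  Each block's voxel values are the mean over
    the volumes inside [onset, onset + duration); the baseline is the mean
    over the fixation window of ``inter_block_fixation_s`` seconds ending
    at the block onset (clipped to the run start).
    """
    import nibabel as nib

    required = {"run", "onset_s", "duration_s", "condition"}
    missing = required - set(timing.columns)
    if missing:
        raise ValueError(f"timing table missing column(s): {sorted(missing)}")
    img = nib.load(str(bold_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D BOLD image, got shape {data.shape}")
    if data.shape[:3] != space.shape:
        raise ValueError(
            f"BOLD grid {data.shape[:3]} does not match mask grid {space.shape}"
        )
    n_vol = data.shape[3]
    flat = data[space.mask]  # (n_voxels, n_vol)
    blocks: list[BlockSeries] = []
    for i, row in timing.reset_index(drop=True).iterrows():
        v0 = int(np.floor(row["onset_s"] / tr_s))
        v1 = int(np.ceil((row["onset_s"] + row["duration_s"]) / tr_s))
        f0 = int(np.floor(max(0.0, row["onset_s"] - inter_block_fixation_s) / tr_s))
        v0, v1 = max(0, v0), min(n_vol, v1)
        if v1 <= v0:
            raise ValueError(f"block row {i}: empty volume window [{v0}, {v1})")
        fix = flat[:, f0:v0].mean(axis=1) if v0 > f0 else None
        blocks.append(
            BlockSeries(
                subject_id=subject_id,
                run=int(row["run"]),
                block=int(i),
                condition=str(row["condition"]),
                voxel_values=flat[:, v0:v1].mean(axis=1),
                preceding_fixation=fix,
            )
        )
    return blocks


def write_synthetic_dataset(dataset, space: VoxelSpace, out_dir: str | Path) -> Path:
    """Serialize a synthetic dataset: mask + per-subject condition NIfTIs,
    behavioral CSV and the ground-truth manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    space.write_mask(out / "mask.nii.gz")
    for s in dataset.subjects:
        for j, c in enumerate(s.conditions):
            space.write_map(s.matrix[:, j], out / f"{s.subject_id}_{c}.nii.gz")
    if len(dataset.behavioral):
        dataset.behavioral.to_csv(out / "behavioral.csv", index=False)
    dataset.write_truth(out / "truth.json")
    return out
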