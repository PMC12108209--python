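"""End-to-end orchestration: calibration, ROI quantification, redox-potential
tables and phenotype statistics reports from a single config.

All outputs are CSV (with ``#``-prefixed provenance headers embedding the
config hash and seed) plus optional heatmap PNGs.  Running twice with the
same config and seed produces byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biosensor, imaging, stats
from .biosensor import CalibrationState, RoGFPConstants
from .simulate import TRAITS

__all__ = ["RunConfig", "run_redox_table", "run_phenotype_report"]

DERIVED_TRAITS = ["lateral_root_density"]
INTENSITY_TRAITS = [
    "root_ros", "shoot_ros", "root_vitality", "shoot_vitality", "root_superoxide",
]


class CalibrationMissingError(KeyError):
    """A batch in the image manifest has no calibration entry."""


@dataclass
class RunConfig:
    """Parsed run configuration.

    Attributes mirror the config file: input manifests, constants overrides,
    calibration source, output directory and seed.
    """

    outdir: Path
    seed: int = 0
    constants: RoGFPConstants = field(default_factory=RoGFPConstants)
    images_manifest: Path | None = None
    roi_table: Path | None = None
    calibration_table: Path | None = None
    phenotype_table: Path | None = None
    control_genotype: str = "Col-0"
    control_treatment: str = "control"
    traits: list = field(default_factory=lambda: TRAITS + DERIVED_TRAITS)
    invert_intensity_factor: bool = False
    heatmaps: bool = True
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent

        def resolve(key_path, default=None):
            node = raw
            for key in key_path:
                if not isinstance(node, dict) or key not in node:
                    return default
                node = node[key]
            return node

        def respath(value):
            if value is None:
                return None
            p = Path(value)
            return p if p.is_absolute() else base / p

        cfg = cls(
            outdir=respath(raw.get("outdir", "out")),
            seed=int(raw.get("seed", 0)),
            constants=biosensor.constants_from_mapping(raw.get("constants", {})),
            images_manifest=respath(resolve(("redox", "images"))),
            roi_table=respath(resolve(("redox", "rois"))),
            calibration_table=respath(resolve(("redox", "calibration"))),
            phenotype_table=respath(resolve(("phenotype", "table"))),
            control_genotype=resolve(("phenotype", "control", "genotype"), "Col-0"),
            control_treatment=resolve(("phenotype", "control", "treatment"), "control"),
            invert_intensity_factor=bool(raw.get("invert_intensity_factor", False)),
            heatmaps=bool(resolve(("phenotype", "heatmaps"), True)),
            raw=raw,
        )
        traits = resolve(("phenotype", "traits"))
        if traits:
            cfg.traits = list(traits)
        return cfg

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _provenance_header(config: RunConfig) -> str:
    return f"# config_hash: {config.config_hash}\n# seed: {config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, **kwargs) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=kwargs.pop("index", False), **kwargs)


def read_output_csv(path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the provenance header."""
    return pd.read_csv(path, comment="#")


def _load_calibrations(path) -> dict[str, CalibrationState]:
    df = pd.read_csv(path)
    required = {"batch", "r_red", "r_ox", "i488_red", "i488_ox"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    return {
        str(row["batch"]): CalibrationState(
            r_red=float(row["r_red"]),
            r_ox=float(row["r_ox"]),
            i488_red=float(row["i488_red"]),
            i488_ox=float(row["i488_ox"]),
        )
        for _, row in df.iterrows()
    }


def quantify_rois(config: RunConfig) -> pd.DataFrame:
    """Per-image biosensor quantification: ratio, OxD, E_GSH for each sample ROI.

    The image manifest needs columns (image_id, path, genotype, organ, batch);
    ROI definitions follow the (image_id, channel, cx_um, cy_um, radius_um,
    role) convention, with role=background ROIs supplying per-channel
    background levels.
    """
    manifest = pd.read_csv(config.images_manifest)
    rois = imaging.read_roi_table(config.roi_table)
    calibs = _load_calibrations(config.calibration_table)
    base = config.images_manifest.parent

    records = []
    for _, img_row in manifest.iterrows():
        image_id = str(img_row["image_id"])
        batch = str(img_row["batch"])
        if batch not in calibs:
            raise CalibrationMissingError(
                f"no calibration for batch {batch!r} (image {image_id!r})"
            )
        path = Path(img_row["path"])
        stack = imaging.read_tiff_stack(path if path.is_absolute() else base / path)
        img_rois = rois[rois["image_id"].astype(str) == image_id]
        backgrounds: dict[str, float] = {}
        for _, r in img_rois[img_rois["role"] == "background"].iterrows():
            roi = imaging.CircularROI(cx=r["cx_um"], cy=r["cy_um"], radius=r["radius_um"])
            res = imaging.roi_mean(
                stack.channels[r["channel"]], roi, 0.0, pixel_size=stack.pixel_size
            )
            backgrounds[r["channel"]] = res.mean_intensity
        for _, r in img_rois[img_rois["role"] == "sample"].iterrows():
            roi = imaging.CircularROI(cx=r["cx_um"], cy=r["cy_um"], radius=r["radius_um"])
            meas = imaging.ratio_measurement(stack, roi, backgrounds)
            oxd_res = biosensor.compute_oxd(
                meas, calibs[batch],
                invert_intensity_factor=config.invert_intensity_factor,
            )
            egsh = biosensor.egsh_from_oxd(oxd_res.oxd, config.constants)
            records.append(
                {
                    "image_id": image_id,
                    "genotype": img_row["genotype"],
                    "organ": img_row["organ"],
                    "batch": batch,
                    "ratio": meas.ratio,
                    "oxd": oxd_res.oxd,
                    "egsh_mV": round(egsh, 2),
                    "flags": ";".join(oxd_res.flags),
                }
            )
    return pd.DataFrame(records)


def run_redox_table(config: RunConfig) -> pd.DataFrame:
    """Per-genotype, per-organ E_GSH table: mean ± SD (mV) with Duncan letters.

    One row per genotype; per organ a formatted ``mean ± SD letters`` cell
    (mV to 2 decimals), with the per-ROI table written alongside.
    """
    per_roi = quantify_rois(config)
    out = config.outdir
    _write_csv(per_roi, out / "redox_per_roi.csv", config)

    rows = {}
    for organ, organ_df in per_roi.groupby("organ", sort=True):
        groups = {
            g: sub["egsh_mV"].to_numpy()
            for g, sub in organ_df.groupby("genotype", sort=True)
        }
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            letters = stats.duncan_mrt(groups).letters
        else:
            letters = {g: "" for g in groups}
        for g, vals in groups.items():
            mean = vals.mean()
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            rows.setdefault(g, {})[organ] = (
                f"{mean:.2f} ± {sd:.2f} {letters[g]}".strip()
            )
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "genotype"
    _write_csv(table.reset_index(), out / "redox_table.csv", config)
    return table


def run_phenotype_report(config: RunConfig) -> dict:
    """Phenotype statistics report.

    Per trait: one-way ANOVA across genotype × treatment groups, Duncan
    letters, group means ± SE, and control% normalization of intensity
    traits against the untreated control genotype.  Per genotype (pooling
    treatments) and overall: Pearson correlation matrices, written
    long-format and optionally rendered as blue-positive / red-negative
    heatmaps.  Zero-variance traits are skipped with a warning flag.
    """
    table = pd.read_csv(config.phenotype_table, comment="#")
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)

    if (
        "lateral_root_density" in config.traits
        and "lateral_root_density" not in table.columns
        and {"lateral_root_count", "primary_root_length"} <= set(table.columns)
    ):
        table["lateral_root_density"] = stats.lateral_root_density(
            table["lateral_root_count"], table["primary_root_length"]
        )

    control_mask = (table["genotype"] == config.control_genotype) & (
        table["treatment"] == config.control_treatment
    )
    if not control_mask.any():
        raise ValueError(
            f"no control rows ({config.control_genotype}, {config.control_treatment})"
        )

    # control% columns for the dye-intensity traits
    for trait in INTENSITY_TRAITS:
        if trait in table.columns:
            table[f"{trait}_pct"] = imaging.percent_of_control(
                table[trait], table.loc[control_mask, trait]
            )

    stat_rows = []
    skipped = []
    for trait in config.traits:
        if trait not in table.columns:
            continue
        groups = {
            f"{g}|{t}": sub[trait].to_numpy(dtype=float)
            for (g, t), sub in table.groupby(["genotype", "treatment"], sort=True)
        }
        if all(np.var(v) == 0.0 for v in groups.values()):
            skipped.append(trait)
            continue
        res = stats.duncan_mrt(groups)
        ctrl_key = f"{config.control_genotype}|{config.control_treatment}"
        ctrl_mean = res.group_means.get(ctrl_key, np.nan)
        for key in sorted(groups):
            g, t = key.split("|", 1)
            vals = groups[key]
            stat_rows.append(
                {
                    "trait": trait,
                    "genotype": g,
                    "treatment": t,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "se": vals.std(ddof=1) / np.sqrt(len(vals)),
                    "pct_of_control": 100.0 * vals.mean() / ctrl_mean
                    if ctrl_mean and np.isfinite(ctrl_mean) and ctrl_mean > 0
                    else np.nan,
                    "letters": res.letters[key],
                    "anova_F": res.anova.f_statistic,
                    "anova_p": res.anova.p_value,
                }
            )
    stats_df = pd.DataFrame(stat_rows)
    _write_csv(stats_df, out / "phenotype_stats.csv", config)

    corr_traits = [t for t in config.traits if t in table.columns]
    matrices = stats.pearson_matrix(table, corr_traits, grouping="per-genotype")
    matrices.update(stats.pearson_matrix(table, corr_traits, grouping="overall"))
    long_rows = []
    for name, mat in sorted(matrices.items()):
        for a in mat.index:
            for b in mat.columns:
                long_rows.append(
                    {"group": name, "trait_a": a, "trait_b": b, "r": mat.at[a, b]}
                )
    corr_df = pd.DataFrame(long_rows)
    _write_csv(corr_df, out / "correlations.csv", config)

    if config.heatmaps:
        _render_heatmaps(matrices, out / "heatmaps")

    return {
        "stats": stats_df,
        "correlations": matrices,
        "skipped_traits": skipped,
        "table": table,
    }


def _render_heatmaps(matrices: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    for name, mat in matrices.items():
        fig, ax = plt.subplots(figsize=(6, 5))
        # RdBu: positive correlations blue, negative red
        im = ax.imshow(mat.to_numpy(dtype=float), cmap="RdBu", vmin=-1, vmax=1)
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(mat.index)), mat.index, fontsize=7)
        ax.set_title(f"Pearson r — {name}")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(outdir / f"correlation_{name.replace('|', '_')}.png", dpi=120)
        plt.close(fig)
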