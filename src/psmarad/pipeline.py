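"""End-to-end pipeline: simulate -> preprocess -> perturb -> extract ->
stability -> pair -> model -> report.

Every stage is a function from input files to output files, so each can be
re-run standalone on a previous stage's directory. ``run_all`` chains them
under a single master seed: stage seeds are derived deterministically as
``SeedSequence([master_seed, stage_index])`` (stage 0 = simulation,
stage 1 = modeling), so a stage re-run in isolation reproduces the
full-run results. A manifest records the config snapshot, seed, package
version and SHA-256 of every output file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import ALL_FEATURES, extract_all
from .modeling import MODEL_IDS, MODEL_NAMES, ModelConfig, SuiteResults, build_model_suite
from .pairing import join_histology_labels, pair_lesions, pairs_frame
from .perturb import variant_family
from .stability import stability_filter
from .synthetic import CohortConfig, generate_cohort
from .volumes import (
    MOD_MRI,
    MOD_PET,
    VARIANTS,
    LesionMask,
    read_mask,
    read_volume,
    resample_isotropic,
    write_mask,
    write_volume,
)

VARIANT_SUFFIX = {"minus1": "m1", "orig": "orig", "plus1": "p1", "plus2": "p2"}
SUFFIX_VARIANT = {v: k for k, v in VARIANT_SUFFIX.items()}
PET_POSITIVITY_SUV = 3.0

FEATURE_COLUMNS = ["patient_id", "lesion_id", "modality", "variant", "feature", "value"]


def _stage_seed(master_seed: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([master_seed, stage_index]).generate_state(1)[0] % (2**31))


def _patient_of(lesion_id: str) -> str:
    return lesion_id.split("_")[0]


def _mask_files(directory: Path) -> list[Path]:
    return sorted(directory.glob("*.nii.gz")) if directory.exists() else []


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: CohortConfig, out_dir: str | Path) -> Path:
    return generate_cohort(config, out_dir)


def stage_preprocess(cohort_dir: str | Path, out_dir: str | Path) -> Path:
    """Resample all volumes and masks to the common 1 mm isotropic grid and
    apply the PET positivity rule (lesion SUVmax >= 3 g/mL); PET lesions
    failing it are dropped and logged."""
    cohort_dir, out = Path(cohort_dir), Path(out_dir)
    log_rows = []
    pet_volumes = {}
    for sub, modality in (("pet", MOD_PET), ("mri", MOD_MRI)):
        for f in sorted((cohort_dir / sub).glob("*.nii.gz")):
            vol = resample_isotropic(read_volume(f, modality))
            write_volume(vol, out / sub / f.name)
            if modality == MOD_PET:
                pet_volumes[f.name.replace(".nii.gz", "")] = vol
    for sub, modality in (("masks_pet", MOD_PET), ("masks_mri", MOD_MRI)):
        for f in _mask_files(cohort_dir / sub):
            lid = f.name.replace(".nii.gz", "")
            mask = read_mask(f, patient_id=_patient_of(lid), lesion_id=lid, modality=modality)
            mask = resample_isotropic(mask)
            if mask.voxel_count() == 0:
                log_rows.append(dict(lesion_id=lid, modality=modality, action="dropped", reason="empty after resampling"))
                continue
            if modality == MOD_PET:
                suvmax = float(pet_volumes[mask.patient_id].values[mask.bool()].max())
                if suvmax < PET_POSITIVITY_SUV:
                    log_rows.append(
                        dict(lesion_id=lid, modality=modality, action="dropped",
                             reason=f"SUVmax {suvmax:.2f} < {PET_POSITIVITY_SUV} g/mL")
                    )
                    continue
            write_mask(mask, out / sub / f.name)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(log_rows, columns=["lesion_id", "modality", "action", "reason"]).to_csv(
        out / "preprocess_log.csv", index=False
    )
    for aux in ("ground_truth.csv", "config.yaml"):
        if (cohort_dir / aux).exists():
            (out / aux).write_bytes((cohort_dir / aux).read_bytes())
    return out


def stage_perturb(pre_dir: str | Path, out_dir: str | Path) -> Path:
    """Write the four contour variants of every mask; degenerate
    contractions are logged instead of written."""
    pre, out = Path(pre_dir), Path(out_dir)
    log_rows = []
    for sub, modality in (("masks_pet", MOD_PET), ("masks_mri", MOD_MRI)):
        for f in _mask_files(pre / sub):
            lid = f.name.replace(".nii.gz", "")
            mask = read_mask(f, patient_id=_patient_of(lid), lesion_id=lid, modality=modality)
            for variant, vmask in variant_family(mask).items():
                if vmask.degenerate:
                    log_rows.append(dict(lesion_id=lid, modality=modality, variant=variant, status="degenerate"))
                    continue
                write_mask(vmask, out / sub / f"{lid}_{VARIANT_SUFFIX[variant]}.nii.gz")
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(log_rows, columns=["lesion_id", "modality", "variant", "status"]).to_csv(
        out / "perturb_log.csv", index=False
    )
    return out


def _extract_one(volume, mask, n_bins: int) -> list[dict]:
    fv = extract_all(volume, mask, n_bins=n_bins)
    return [
        dict(
            patient_id=mask.patient_id,
            lesion_id=mask.lesion_id,
            modality=mask.modality,
            variant=mask.variant,
            feature=name,
            value=np.nan if value is None else value,
        )
        for name, value in fv.values.items()
    ]


def stage_extract(pre_dir: str | Path, variants_dir: str | Path, out_csv: str | Path, n_bins: int = 32) -> Path:
    """Extract the feature battery for every (lesion, modality, variant)."""
    pre, var = Path(pre_dir), Path(variants_dir)
    rows: list[dict] = []
    for sub, modality in (("masks_pet", MOD_PET), ("masks_mri", MOD_MRI)):
        volumes = {}
        for f in _mask_files(var / sub):
            stem = f.name.replace(".nii.gz", "")
            lid, suffix = stem.rsplit("_", 1)
            variant = SUFFIX_VARIANT[suffix]
            pid = _patient_of(lid)
            if pid not in volumes:
                vol_sub = "pet" if modality == MOD_PET else "mri"
                volumes[pid] = read_volume(pre / vol_sub / f"{pid}.nii.gz", modality)
            mask = read_mask(f, patient_id=pid, lesion_id=lid, modality=modality, variant=variant)
            rows.extend(_extract_one(volumes[pid], mask, n_bins))
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(out_csv, index=False)
    return out_csv


def stage_stability(features_csv: str | Path, out_dir: str | Path, threshold: float = 0.6) -> Path:
    """Per-modality ICC screening of the contour-variant feature tables."""
    feats = pd.read_csv(features_csv)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for modality, tag in ((MOD_PET, "pet"), (MOD_MRI, "mri")):
        sub = feats[feats["modality"] == modality]
        if sub.empty:
            stable, report = [], pd.DataFrame(columns=["feature", "icc", "n_lesions", "n_variants", "passed"])
        else:
            stable, report = stability_filter(sub, threshold=threshold)
        report.to_csv(out / f"stability_{tag}.csv", index=False)
        (out / f"stable_{tag}.txt").write_text("\n".join(stable) + ("\n" if stable else ""))
    return out


def _crop_to_common_grid(
    pet_masks: dict[str, LesionMask], mri_masks: dict[str, LesionMask]
) -> tuple[dict[str, LesionMask], dict[str, LesionMask]]:
    """Crop both resampled mask sets to the shared grid (elementwise minimum
    shape). Requires identical spacing and origin; grid extents may differ
    by a voxel when the native slice thicknesses do not divide the frame."""
    if not pet_masks or not mri_masks:
        return pet_masks, mri_masks
    pm = next(iter(pet_masks.values()))
    mm = next(iter(mri_masks.values()))
    if not (np.allclose(pm.spacing, mm.spacing) and np.allclose(pm.origin, mm.origin, atol=1e-6)):
        raise ValueError(
            f"PET and MRI masks are not on a common frame (spacing {pm.spacing} vs {mm.spacing}, "
            f"origin {pm.origin} vs {mm.origin})"
        )
    shape = tuple(min(a, b) for a, b in zip(pm.shape, mm.shape))
    box = tuple(slice(0, s) for s in shape)

    def crop(masks: dict[str, LesionMask]) -> dict[str, LesionMask]:
        out = {}
        for lid, m in masks.items():
            if m.shape == shape:
                out[lid] = m
            else:
                vals = m.values[box]
                out[lid] = m.replace(values=vals, degenerate=not vals.any())
        return out

    return crop(pet_masks), crop(mri_masks)


def stage_pair(pre_dir: str | Path, out_dir: str | Path) -> Path:
    """Pair PET and MRI lesions per patient and write the resolved final masks."""
    pre, out = Path(pre_dir), Path(out_dir)
    by_patient: dict[str, tuple[dict, dict]] = {}
    for sub, modality, slot in (("masks_pet", MOD_PET, 0), ("masks_mri", MOD_MRI, 1)):
        for f in _mask_files(pre / sub):
            lid = f.name.replace(".nii.gz", "")
            pid = _patient_of(lid)
            mask = read_mask(f, patient_id=pid, lesion_id=lid, modality=modality)
            by_patient.setdefault(pid, ({}, {}))[slot][lid] = mask
    all_pairs = []
    for pid in sorted(by_patient):
        pet_masks, mri_masks = by_patient[pid]
        pet_masks, mri_masks = _crop_to_common_grid(pet_masks, mri_masks)
        for pair in pair_lesions(pet_masks, mri_masks):
            all_pairs.append(pair)
            write_mask(pair.pet_mask, out / "paired_masks_pet" / f"{pair.pet_lesion_id}.nii.gz")
            write_mask(pair.mri_mask, out / "paired_masks_mri" / f"{pair.mri_lesion_id}.nii.gz")
    out.mkdir(parents=True, exist_ok=True)
    pairs_frame(all_pairs).to_csv(out / "pairs.csv", index=False)
    return out


def stage_extract_paired(pre_dir: str | Path, pair_dir: str | Path, out_csv: str | Path, n_bins: int = 32) -> Path:
    """Feature extraction on the pairing-resolved final masks."""
    pre, pair_dir = Path(pre_dir), Path(pair_dir)
    pairs = pd.read_csv(pair_dir / "pairs.csv")
    rows: list[dict] = []
    volumes: dict[tuple[str, str], object] = {}
    for _, row in pairs.iterrows():
        for modality, sub, vol_sub, lid in (
            (MOD_PET, "paired_masks_pet", "pet", row["pet_lesion_id"]),
            (MOD_MRI, "paired_masks_mri", "mri", row["mri_lesion_id"]),
        ):
            pid = row["patient_id"]
            key = (pid, modality)
            if key not in volumes:
                volumes[key] = read_volume(pre / vol_sub / f"{pid}.nii.gz", modality)
            mask = read_mask(pair_dir / sub / f"{lid}.nii.gz", patient_id=pid, lesion_id=lid, modality=modality)
            rows.extend(_extract_one(volumes[key], mask, n_bins))
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(out_csv, index=False)
    return out_csv


def _wide(features: pd.DataFrame, modality: str, stable: list[str]) -> pd.DataFrame:
    sub = features[(features["modality"] == modality) & (features["variant"] == "orig")]
    if sub.empty or not stable:
        return pd.DataFrame()
    wide = sub.pivot_table(index="lesion_id", columns="feature", values="value", aggfunc="first")
    cols = [c for c in stable if c in wide.columns]
    return wide[cols]


def stage_model(
    features_csv: str | Path,
    paired_features_csv: str | Path,
    stability_dir: str | Path,
    pairs_csv: str | Path,
    ground_truth_csv: str | Path,
    out_dir: str | Path,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> SuiteResults:
    """Assemble the five lesion datasets, fit the model suite and write the
    summary, per-iteration records, selection frequencies and best-iteration
    ROC coordinates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = pd.read_csv(features_csv)
    paired_feats = pd.read_csv(paired_features_csv)
    gt = pd.read_csv(ground_truth_csv)
    pairs = pd.read_csv(pairs_csv)
    stable = {
        tag: [
            line
            for line in (Path(stability_dir) / f"stable_{tag}.txt").read_text().splitlines()
            if line.strip()
        ]
        for tag in ("pet", "mri")
    }

    # histology join: false-positive contours are discarded, the rest get
    # the binary ISUP 1 vs 2+ label
    def labeled(lesion_ids: pd.Index) -> pd.DataFrame:
        df = pd.DataFrame({"lesion_id": lesion_ids})
        return join_histology_labels(df, gt).set_index("lesion_id")

    wide_pet = _wide(feats, MOD_PET, stable["pet"])
    wide_mri = _wide(feats, MOD_MRI, stable["mri"])
    paired_pet = _wide(paired_feats, MOD_PET, stable["pet"])
    paired_mri = _wide(paired_feats, MOD_MRI, stable["mri"])
    # a pair is analysed only when both its lesions survived the label join
    if not paired_pet.empty and not paired_mri.empty:
        pet_ok = labeled(paired_pet.index).index
        mri_ok = labeled(paired_mri.index).index
        keep = pairs[pairs["pet_lesion_id"].isin(pet_ok) & pairs["mri_lesion_id"].isin(mri_ok)]
        paired_pet = paired_pet.loc[paired_pet.index.isin(keep["pet_lesion_id"])]
        paired_mri_by_pet = keep.set_index("pet_lesion_id")["mri_lesion_id"]
        paired_mri = paired_mri.loc[paired_mri_by_pet.loc[paired_pet.index]]
        paired_mri.index = paired_pet.index  # both tables indexed by the pair's PET lesion

    labels_parts = []
    for table in (wide_pet, wide_mri, paired_pet):
        if not table.empty:
            lab = labeled(table.index)
            labels_parts.append(lab["label"])
    labels = pd.concat(labels_parts).groupby(level=0).first() if labels_parts else pd.Series(dtype=int)
    # restrict every table to lesions that survived the histology join
    wide_pet = wide_pet.loc[wide_pet.index.intersection(labels.index)] if not wide_pet.empty else wide_pet
    wide_mri = wide_mri.loc[wide_mri.index.intersection(labels.index)] if not wide_mri.empty else wide_mri
    if not paired_pet.empty:
        keep_idx = paired_pet.index.intersection(labels.index)
        paired_pet, paired_mri = paired_pet.loc[keep_idx], paired_mri.loc[keep_idx]

    groups = pd.Series({lid: _patient_of(lid) for lid in labels.index}) if not labels.empty else None
    suite = build_model_suite(
        wide_pet, wide_mri, paired_pet, paired_mri, labels,
        config=config, seed=seed, groups=groups,
    )
    suite.summary_frame().to_csv(out / "summary.csv", index=False)
    (out / "skipped.json").write_text(json.dumps(suite.skipped, indent=2, sort_keys=True))
    for mid, res in suite.results.items():
        res.iterations.drop(columns=["selected"]).to_csv(out / f"iterations_{mid}.csv", index=False)
        res.selection_frequencies.rename_axis("feature").reset_index().to_csv(
            out / f"selection_frequencies_{mid}.csv", index=False
        )
        roc_train, roc_test = res.best_roc()
        roc_train.to_csv(out / f"roc_best_{mid}_train.csv", index=False)
        roc_test.to_csv(out / f"roc_best_{mid}_test.csv", index=False)
    return suite


# ---------------------------------------------------------------------------
# orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def output_hashes(run_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every output file under a run directory (manifest and
    report excluded)."""
    run_dir = Path(run_dir)
    out = {}
    for f in sorted(run_dir.rglob("*")):
        if f.is_file() and f.name not in ("manifest.json", "report.md"):
            out[str(f.relative_to(run_dir))] = _sha256(f)
    return out


def run_all(
    config: CohortConfig | str | Path | None,
    out_dir: str | Path,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    n_bins: int = 32,
) -> Path:
    """Run the complete pipeline into ``out_dir`` and write manifest + report."""
    if config is None:
        config = CohortConfig()
    elif isinstance(config, (str, Path)):
        config = CohortConfig.from_yaml(config)
    import dataclasses as _dc

    config = _dc.replace(config, seed=_stage_seed(seed, 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # stale stage outputs from a previous run would corrupt the manifest
    import shutil

    for sub in ("cohort", "preprocessed", "variants", "features", "stability", "pairs", "models"):
        shutil.rmtree(out / sub, ignore_errors=True)

    cohort_dir = stage_simulate(config, out / "cohort")
    pre_dir = stage_preprocess(cohort_dir, out / "preprocessed")
    var_dir = stage_perturb(pre_dir, out / "variants")
    features_csv = stage_extract(pre_dir, var_dir, out / "features" / "features.csv", n_bins)
    stability_dir = stage_stability(features_csv, out / "stability")
    pair_dir = stage_pair(pre_dir, out / "pairs")
    paired_csv = stage_extract_paired(pre_dir, pair_dir, out / "features" / "paired_features.csv", n_bins)
    stage_model(
        features_csv,
        paired_csv,
        stability_dir,
        pair_dir / "pairs.csv",
        pre_dir / "ground_truth.csv",
        out / "models",
        config=model_config,
        seed=_stage_seed(seed, 1),
    )

    manifest = dict(
        seed=int(seed),
        version=__version__,
        config=(out / "cohort" / "config.yaml").read_text(),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        hashes=output_hashes(out),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.md").write_text(report(out))
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable markdown summary of a completed (or partial) run."""
    run_dir = Path(run_dir)
    lines = ["# Pipeline report", ""]

    summary_csv = run_dir / "models" / "summary.csv"
    lines.append("## Models")
    lines.append("")
    if summary_csv.exists():
        df = pd.read_csv(summary_csv)
        header = ["Model Type", "Number of Lesions", "Train Mean AUC", "Test Mean AUC", "Train Best AUC", "Test Best AUC"]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for _, r in df.iterrows():
            lines.append(
                f"| {r['model_type']} | {r['n_lesions']} | {r['train_mean_auc']} | "
                f"{r['test_mean_auc']} | {r['train_best_auc']} | {r['test_best_auc']} |"
            )
        if df.empty:
            lines.append("")
            lines.append("No model could be fitted (zero usable features or lesions).")
    else:
        lines.append("*missing: models/summary.csv*")
    skipped_json = run_dir / "models" / "skipped.json"
    if skipped_json.exists():
        skipped = json.loads(skipped_json.read_text())
        for mid, reason in sorted(skipped.items()):
            lines.append(f"- model ({mid}) {MODEL_NAMES.get(mid, mid)} skipped: {reason}")
    lines.append("")

    lines.append("## Most frequently selected features")
    lines.append("")
    found = False
    for mid in MODEL_IDS:
        f = run_dir / "models" / f"selection_frequencies_{mid}.csv"
        if not f.exists():
            continue
        found = True
        df = pd.read_csv(f).head(10)
        lines.append(f"**({mid}) {MODEL_NAMES[mid]}**")
        for _, r in df.iterrows():
            lines.append(f"- {r['feature']}: {r['selection_frequency']:.2f}")
        lines.append("")
    if not found:
        lines.append("*no selection-frequency tables*")
        lines.append("")

    lines.append("## Feature stability (ICC > 0.6)")
    lines.append("")
    for tag, label in (("pet", "PET"), ("mri", "MRI-ADC")):
        f = run_dir / "stability" / f"stability_{tag}.csv"
        if f.exists():
            df = pd.read_csv(f)
            lines.append(f"- {label}: {int(df['passed'].sum())} of {len(df)} features passed")
        else:
            lines.append(f"- {label}: *missing stability report*")
    lines.append("")

    pairs_csv = run_dir / "pairs" / "pairs.csv"
    lines.append("## Lesion pairing")
    lines.append("")
    if pairs_csv.exists():
        df = pd.read_csv(pairs_csv)
        lines.append(f"- {len(df)} PET/MRI lesion pairs")
        if len(df):
            for rule, cnt in df["rule"].value_counts().items():
                lines.append(f"  - {rule}: {cnt}")
    else:
        lines.append("*missing pairs.csv*")
    lines.append("")
    return "\n".join(lines)
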