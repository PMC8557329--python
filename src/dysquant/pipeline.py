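"""End-to-end orchestration: image in, per-fiber / section / cohort CSVs out.

Every output directory receives the resolved config, a run log and input
checksums so runs are fully reproducible.
"""

from __future__ import annotations

import hashlib
import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from dysquant import fiberquant, segment, summarize
from dysquant.config import PipelineConfig
from dysquant.simulate import SectionImage
from dysquant.stats import exact_mann_whitney
from dysquant.summarize import SectionSummary, SubjectRecord


class PipelineError(ValueError):
    pass


class ChannelError(PipelineError):
    pass


def read_section(
    path: str,
    dys_channel: str | int = "DYS",
    lam_channel: str | int = "LAMA2",
) -> SectionImage:
    """Read a two-channel (OME-)TIFF; channels resolved by name or index."""
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
    except (FileNotFoundError, tifffile.TiffFileError) as exc:
        raise PipelineError(f"cannot read image {path}: {exc}") from exc
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ChannelError(f"{path}: expected a (C, H, W) stack, got {arr.shape}")
    if arr.shape[0] > arr.shape[-1]:  # channels last → first
        arr = np.moveaxis(arr, -1, 0)

    def resolve(spec: str | int) -> int:
        if isinstance(spec, int) or str(spec).lstrip("-").isdigit():
            idx = int(spec)
            if not 0 <= idx < arr.shape[0]:
                raise ChannelError(f"{path}: channel index {idx} out of range")
            return idx
        # by conventional name: DYS first, LAMA2 second
        names = {"DYS": 0, "LAMA2": 1}
        if spec not in names or names[spec] >= arr.shape[0]:
            raise ChannelError(f"{path}: channel {spec!r} not found")
        return names[spec]

    di, li = resolve(dys_channel), resolve(lam_channel)
    if di == li:
        raise ChannelError(f"{path}: dystrophin and laminin map to one channel")
    pixels = np.stack([arr[di], arr[li]]).astype(np.uint16)
    return SectionImage(pixels, ("DYS", "LAMA2"))


def quantify_image(
    image: SectionImage, config: PipelineConfig
) -> tuple[pd.DataFrame, SectionSummary]:
    """Segment, ring-extract and quantify one section image."""
    label_map = segment.segment_fibers(
        image.laminin,
        min_area=config.min_area,
        laminin_threshold=config.laminin_threshold,
        border_margin=config.border_margin,
        expand_px=config.ring_width + 2,
    )
    if label_map.n_labels == 0:
        raise PipelineError("no fibers segmented after exclusions")
    rings = segment.extract_ring(
        label_map, ring_width=config.ring_width, n_arcs=config.n_arcs
    )
    if config.positivity_threshold == "auto":
        threshold = fiberquant.auto_positivity_threshold(image.dystrophin, label_map)
    else:
        threshold = float(config.positivity_threshold)
    fibers = fiberquant.quantify_fibers(
        image.dystrophin,
        rings,
        threshold,
        smooth_window=config.smooth_window,
        relative_fraction=config.positivity_relative_fraction,
        pool_window=config.pool_window,
    )
    meta = {
        "laminin_threshold": label_map.threshold,
        "positivity_threshold": threshold,
        "n_border_excluded": label_map.n_border_excluded,
        "n_small_excluded": label_map.n_small_excluded,
    }
    return fibers, summarize.summarize_section(fibers, metadata=meta)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_quantify(
    image_path: str, config: PipelineConfig, out_dir: str
) -> tuple[pd.DataFrame, SectionSummary]:
    """Quantify one section image and write fibers.csv / summary.csv with
    full provenance (config.yaml, run.log, input checksum)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image = read_section(image_path, config.dys_channel, config.lam_channel)
    fibers, summary = quantify_image(image, config)
    fibers.to_csv(out / "fibers.csv", index=False)
    summarize.section_summary_frame(summary).to_csv(out / "summary.csv", index=False)
    config.to_yaml(str(out / "config.yaml"))
    with open(out / "run.log", "w") as log:
        log.write(f"input: {image_path}\n")
        log.write(f"sha256: {_sha256(image_path)}\n")
        for key, value in summary.metadata.items():
            log.write(f"{key}: {value}\n")
        log.write(f"n_fibers: {summary.n_fibers}\n")
    return fibers, summary


def compare_groups(
    replicate_values: pd.DataFrame,
    metric: str,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Mann–Whitney comparisons on replicate-level values.

    ``replicate_values`` needs columns ``phenotype`` and ``metric`` with one
    row per replicate section (2 per subject).
    """
    if metric not in replicate_values.columns:
        raise PipelineError(f"unknown metric {metric!r}")
    present = list(dict.fromkeys(replicate_values["phenotype"]))
    groups = groups or present
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        xs = replicate_values.loc[replicate_values["phenotype"] == g1, metric]
        ys = replicate_values.loc[replicate_values["phenotype"] == g2, metric]
        cmp = exact_mann_whitney(xs.to_numpy(), ys.to_numpy())
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "metric": metric,
                "n1": cmp.n1,
                "n2": cmp.n2,
                "mean_1": float(xs.mean()),
                "mean_2": float(ys.mean()),
                "U": cmp.u,
                "p": cmp.p,
                "method": cmp.method,
            }
        )
    return pd.DataFrame(rows)


def run_cohort(
    manifest_path: str, config: PipelineConfig, out_dir: str
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Batch-process a cohort manifest into subject and comparison tables.

    The manifest CSV needs columns subject_id, phenotype, image_path with
    exactly 2 rows (replicate serial sections) per subject.  Outputs
    subjects.csv and, when more than one phenotype is present,
    comparisons.csv over replicate-level values for both metrics.
    """
    manifest = pd.read_csv(manifest_path).sort_values(
        ["subject_id", "image_path"], kind="stable"
    )
    required = {"subject_id", "phenotype", "image_path"}
    if missing := required - set(manifest.columns):
        raise PipelineError(f"manifest missing columns: {sorted(missing)}")
    bad = [
        str(sid)
        for sid, grp in manifest.groupby("subject_id")
        if len(grp) != 2
    ]
    if bad:
        raise PipelineError(
            f"subjects without exactly 2 replicate sections: {', '.join(bad)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects: list[SubjectRecord] = []
    replicate_rows = []
    for sid, grp in manifest.groupby("subject_id", sort=True):
        phenotype = str(grp["phenotype"].iloc[0])
        reps = []
        for k, row in enumerate(grp.itertuples(index=False), start=1):
            fibers, summary = run_quantify(
                row.image_path, config, str(out / f"{sid}_rep{k}")
            )
            reps.append(summary)
            replicate_rows.append(
                {
                    "subject_id": sid,
                    "phenotype": phenotype,
                    "replicate": k,
                    "mean_intensity_au": summary.mean_intensity,
                    "pct_positive": summary.pct_positive,
                }
            )
        subjects.append(
            summarize.summarize_subject(reps[0], reps[1], str(sid), phenotype)
        )
    subject_table = summarize.subject_frame(subjects)
    subject_table.to_csv(out / "subjects.csv", index=False)
    replicates = pd.DataFrame(replicate_rows)
    replicates.to_csv(out / "replicates.csv", index=False)
    config.to_yaml(str(out / "config.yaml"))
    if replicates["phenotype"].nunique() < 2:
        (out / "run.log").write_text(
            "single phenotype group: comparison table skipped\n"
        )
        return subject_table, None
    comparisons = pd.concat(
        [
            compare_groups(replicates, "mean_intensity_au"),
            compare_groups(replicates, "pct_positive"),
        ],
        ignore_index=True,
    )
    comparisons.to_csv(out / "comparisons.csv", index=False)
    return subject_table, comparisons
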