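"""Genome scanning, ranking and gene annotation of candidate regions."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from introscan.calibrate import Calibrator
from introscan.encode import encode_panel
from introscan.model import TrainedClassifier, predict
from introscan.windows import GenomeWindow, VcfDataset, load_window

logger = logging.getLogger(__name__)


def scan_genome(
    classifier: TrainedClassifier,
    calibrator: Calibrator | None,
    vcf_set: VcfDataset,
    windows: list[GenomeWindow],
    *,
    order: tuple[str, ...],
    donor: str,
    m: int = 256,
    phased: bool = True,
    freq_min: float = 0.05,
    missing_max: float = 0.10,
    min_seg: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Apply the trained classifier to each window of a VCF dataset.

    Returns one row per window, sorted by (chrom, start), with raw and
    calibrated Pr[AI]; windows rejected by QC keep NaN scores and carry
    the rejection reason in ``status``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    mats = []
    for win in windows:
        panel = load_window(
            vcf_set, win, freq_min=freq_min, missing_max=missing_max, min_seg=min_seg
        )
        if panel is None:
            rows.append((win.chrom, win.start, win.end, "too_few_sites"))
            mats.append(None)
            continue
        resized = encode_panel(
            panel,
            order,
            donor,
            m=m,
            maf=freq_min,
            keep_equal_maf=True,
            window_start=0,
            window_len=win.size,
            phased=phased,
            rng=rng,
        )
        if resized.matrix.shape != classifier.input_shape:
            raise ValueError(
                f"window {win.region}: encoded shape {resized.matrix.shape} does "
                f"not match the classifier input {classifier.input_shape}; check "
                "panel sizes against the training configuration"
            )
        rows.append((win.chrom, win.start, win.end, "ok"))
        mats.append(resized.matrix)
    ok = [i for i, x in enumerate(mats) if x is not None]
    raw = np.full(len(rows), np.nan)
    if ok:
        raw[ok] = predict(classifier, np.stack([mats[i] for i in ok]))
    calibrated = calibrator(raw) if calibrator is not None else raw.copy()
    calibrated[np.isnan(raw)] = np.nan
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "status"])
    df["raw_prob"] = raw
    df["calibrated_prob"] = calibrated
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def top_regions(
    predictions: pd.DataFrame, n: int = 30, merge: bool = True
) -> pd.DataFrame:
    """Top-``n`` windows by calibrated score, with overlapping or
    adjacent windows merged into intervals before reporting.

    Ties are broken by (chrom, start) for determinism.  The merged
    interval keeps the maximum score of its member windows.
    """
    if predictions.empty:
        raise ValueError("predictions table is empty")
    scored = predictions.dropna(subset=["calibrated_prob"]).copy()
    scored = scored.sort_values(
        ["calibrated_prob", "chrom", "start"],
        ascending=[False, True, True],
        kind="stable",
    )
    top = scored.head(n)
    if not merge:
        return top.reset_index(drop=True)
    merged = []
    for _, row in top.sort_values(["chrom", "start"], kind="stable").iterrows():
        if (
            merged
            and merged[-1]["chrom"] == row.chrom
            and row.start <= merged[-1]["end"] + 1
        ):
            merged[-1]["end"] = max(merged[-1]["end"], row.end)
            merged[-1]["score"] = max(merged[-1]["score"], row.calibrated_prob)
        else:
            merged.append(
                {
                    "chrom": row.chrom,
                    "start": int(row.start),
                    "end": int(row.end),
                    "score": float(row.calibrated_prob),
                }
            )
    out = pd.DataFrame(merged)
    return out.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(
    gff3_path,
    source: str | None = "ensembl_havana",
    feature_type: str = "gene",
) -> pd.DataFrame:
    """Extract gene records from a GFF3 file.

    Only rows matching ``source`` (None disables the source filter) and
    ``feature_type`` are kept.  Malformed lines raise with their line
    number.
    """
    rows = []
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}: expected 9 columns")
            chrom, src, ftype, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            if ftype != feature_type or (source is not None and src != source):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"malformed GFF3 line {lineno}: bad coordinates")
            attrs = _parse_gff3_attributes(fields[8])
            name = attrs.get("Name", attrs.get("ID", f"line{lineno}"))
            rows.append((chrom, start_i, end_i, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def annotate_genes(
    regions: pd.DataFrame,
    gff3_path,
    flank: int = 100_000,
    source: str | None = "ensembl_havana",
) -> pd.DataFrame:
    """Genes overlapping each region or its flanks; every gene is
    reported only once, at the first region that claims it."""
    genes = read_gff3_genes(gff3_path, source=source)
    seen: set[str] = set()
    out = []
    for _, reg in regions.iterrows():
        lo, hi = reg.start - flank, reg.end + flank
        hits = genes[
            (genes.chrom.astype(str) == str(reg.chrom))
            & (genes.end >= lo)
            & (genes.start <= hi)
        ]
        names = [g for g in hits.gene if g not in seen]
        seen.update(names)
        out.append(
            {
                "chrom": reg.chrom,
                "start": reg.start,
                "end": reg.end,
                "genes": ";".join(names),
            }
        )
    return pd.DataFrame(out)


def write_predictions(df: pd.DataFrame, path) -> None:
    """BED-like TSV with 1-based inclusive display coordinates plus the
    half-open machine-readable variant."""
    out = df.copy()
    out["start0"] = out["start"] - 1  # half-open companion columns
    out["end0"] = out["end"]
    out.to_csv(path, sep="\t", index=False)


def manhattan_plot(df: pd.DataFrame, path, column: str = "calibrated_prob") -> None:
    """One point per window along the genome, Pr[AI] on the y axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.dropna(subset=[column])
        ax.scatter(sub["start"] + offset, sub[column], s=4)
        offset += int(df[df.chrom == chrom]["end"].max())
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("Pr[AI]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
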