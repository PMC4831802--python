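"""Cell-table and template-bundle file formats.

Cell tables are delimited text (comma or tab, auto-detected) with one row per
cell and the columns listed in :data:`REQUIRED_COLUMNS`.  Raw DNA-content
intensities are arbitrary units; on read they are rescaled per gonad so the
G1 peak sits at 1.0 and 2n content at 2.0 (the mode of the lower half of the
per-gonad intensity range is taken as the G1 peak).  Template libraries are
saved as a plain CSV of bin counts plus a JSON metadata header — everything
stays inspectable text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cycle import CycleParams
from .dormancy import GonadSample
from .labeling import HistogramPair, TemplateLibrary

__all__ = [
    "REQUIRED_COLUMNS",
    "read_cell_tables",
    "write_cell_tables",
    "save_template_library",
    "load_template_library",
    "normalize_dna_content",
]

REQUIRED_COLUMNS = [
    "worm_id",
    "arm",
    "condition",
    "assay",
    "pulse_h",
    "chase_h",
    "label_h",
    "cell_id",
    "dna_content",
    "edu",
    "ph3",
]


class SchemaError(ValueError):
    """Cell table does not conform to the expected schema."""


def normalize_dna_content(raw: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Rescale raw intensities to the [1, 2] content axis by the G1 peak.

    The G1 peak is the mode of the lower half of the intensity range; it maps
    to 1.0 and twice it to 2.0.  Invariant under multiplicative rescaling of
    the raw units.  Output clamped to [1, 2].
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw
    lo, hi = raw.min(), raw.max()
    if hi <= lo:
        return np.ones_like(raw)
    mid = lo + (hi - lo) / 2.0
    lower = raw[raw <= mid]
    counts, edges = np.histogram(lower, bins=n_bins)
    peak = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    if peak <= 0:
        raise SchemaError("G1-peak normalization failed: non-positive peak intensity")
    return np.clip(raw / peak, 1.0, 2.0)


def write_cell_tables(samples: list[GonadSample], path) -> None:
    """Write GonadSamples as one schema-conformant CSV."""
    frames = []
    for g in samples:
        df = g.cells.copy()
        df.insert(0, "worm_id", g.worm_id)
        df.insert(1, "arm", g.arm)
        df.insert(2, "condition", g.condition)
        df.insert(3, "assay", g.assay)
        df.insert(4, "pulse_h", g.pulse_h if g.assay == "pulse_chase" else "")
        df.insert(5, "chase_h", g.chase_h if g.chase_h is not None else "")
        df.insert(6, "label_h", g.label_h if g.label_h is not None else "")
        df.insert(7, "cell_id", [f"{g.worm_id}_{g.arm}_{i}" for i in range(len(df))])
        df["edu"] = df["edu"].astype(int)
        df["ph3"] = df["ph3"].astype(int)
        frames.append(df[REQUIRED_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cell_tables(path, normalize: bool = True) -> list[GonadSample]:
    """Read a cell table into per-gonad samples, grouped by (worm_id, arm).

    Unknown columns are ignored; missing required columns raise a
    :class:`SchemaError` naming them.  EdU and PH3 columns must be binary.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    for col in ("edu", "ph3"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not vals.isin([0, 1]).all():
            bad = df.index[~vals.isin([0, 1])].tolist()[:5]
            raise SchemaError(f"column {col!r} must be 0/1; offending rows: {bad}")
        df[col] = vals.astype(bool)
    df["dna_content"] = pd.to_numeric(df["dna_content"], errors="raise")
    samples = []
    for (worm_id, arm), grp in df.groupby(["worm_id", "arm"], sort=False):
        content = grp["dna_content"].to_numpy()
        if normalize:
            content = normalize_dna_content(content)
        cells = pd.DataFrame(
            {
                "dna_content": content,
                "edu": grp["edu"].to_numpy(),
                "ph3": grp["ph3"].to_numpy(),
            }
        )
        assay = str(grp["assay"].iloc[0])
        chase_h = pd.to_numeric(grp["chase_h"].iloc[0], errors="coerce")
        label_h = pd.to_numeric(grp["label_h"].iloc[0], errors="coerce")
        pulse_h = pd.to_numeric(grp["pulse_h"].iloc[0], errors="coerce")
        samples.append(
            GonadSample(
                worm_id=str(worm_id),
                arm=str(arm),
                condition=str(grp["condition"].iloc[0]),
                assay=assay,
                cells=cells,
                pulse_h=0.0 if pd.isna(pulse_h) else float(pulse_h),
                chase_h=None if pd.isna(chase_h) else float(chase_h),
                label_h=None if pd.isna(label_h) else float(label_h),
            )
        )
    return samples


def save_template_library(lib: TemplateLibrary, directory) -> None:
    """Save a template library as templates.csv + meta.json in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, tmpl in enumerate(lib.templates):
        for b in range(tmpl.n_bins):
            rows.append(
                {
                    "phase_index": j,
                    "bin_index": b,
                    "count_pos": tmpl.counts_pos[b],
                    "count_neg": tmpl.counts_neg[b],
                }
            )
    pd.DataFrame(rows).to_csv(directory / "templates.csv", index=False)
    from dataclasses import asdict

    meta = {
        "params": asdict(lib.params),
        "k": lib.k,
        "pulse_duration": lib.pulse_duration,
        "n_sim": lib.n_sim,
        "noise_cv": lib.noise_cv,
        "bin_edges": lib.bin_edges.tolist(),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def load_template_library(directory) -> TemplateLibrary:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    df = pd.read_csv(directory / "templates.csv")
    edges = np.asarray(meta["bin_edges"], dtype=float)
    templates = []
    for j in range(meta["k"]):
        grp = df[df["phase_index"] == j].sort_values("bin_index")
        templates.append(
            HistogramPair(edges, grp["count_pos"].to_numpy(), grp["count_neg"].to_numpy())
        )
    return TemplateLibrary(
        CycleParams(**meta["params"]),
        meta["k"],
        templates,
        meta["pulse_duration"],
        meta["n_sim"],
        meta["noise_cv"],
    )
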