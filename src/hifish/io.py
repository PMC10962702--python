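"""Plate layout on disk, table writers, and the run manifest.

File naming is ``<well>_f<field>_<channel>_<acquisition>.tif`` with
acquisition ``single`` for the simultaneous protocol and ``dna_pass`` /
``rna_pass`` for the sequential one; this module owns the only parser of
that convention. Tables go out as UTF-8 comma-separated CSV with a header
row, LF endings, ``.`` decimals, and missing distances as the literal token
``NA`` (the convention downstream statistical environments expect).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .images import Acquisition, read_image
from .pipeline import PipelineResult

log = logging.getLogger(__name__)

NA_TOKEN = "NA"
_FILE_RE = re.compile(
    r"^(?P<well>[A-P]\d{2})_f(?P<field>\d+)_(?P<channel>DAPI|DNA|RNA)"
    r"_(?P<acq>single|dna_pass|rna_pass)\.tif{1,2}$"
)


def parse_image_name(name: str) -> dict | None:
    """Decode well/field/channel/acquisition from a file name (or None)."""
    m = _FILE_RE.match(name)
    if not m:
        return None
    d = m.groupdict()
    d["field"] = int(d["field"])
    return d


@dataclass
class PlateLayout:
    """Index of image files under a plate root, grouped per well and field."""

    root: Path
    # (well, field, acq) -> {channel: path}
    groups: dict[tuple[str, int, str], dict[str, Path]] = field(default_factory=dict)

    @property
    def wells(self) -> list[str]:
        return sorted({w for w, _, _ in self.groups})

    def acquisition_tags(self) -> set[str]:
        return {acq for _, _, acq in self.groups}


def scan_plate(root: str | Path) -> PlateLayout:
    """Index a plate directory; warns when it contains no images."""
    root = Path(root)
    layout = PlateLayout(root)
    for path in sorted(root.rglob("*.tif")) + sorted(root.rglob("*.tiff")):
        parsed = parse_image_name(path.name)
        if parsed is None:
            continue
        key = (parsed["well"], parsed["field"], parsed["acq"])
        layout.groups.setdefault(key, {})[parsed["channel"]] = path
    if not layout.groups:
        log.warning("no plate images found under %s", root)
    return layout


_REQUIRED = {
    "single": {"DAPI", "DNA", "RNA"},
    "dna_pass": {"DAPI", "DNA"},
    "rna_pass": {"DAPI", "RNA"},
}


def load_plate(root: str | Path, pixel_size: float, mode: str = "simultaneous"):
    """Load a plate into acquisitions ready for :func:`run_pipeline`.

    Returns single acquisitions (simultaneous) or (DNA-pass, RNA-pass) pairs
    (sequential). Every missing channel or pass across the whole plate is
    collected into one aggregate error.
    """
    layout = scan_plate(root)
    problems: list[str] = []

    def build(well: str, fld: int, acq_tag: str) -> Acquisition | None:
        channels = layout.groups.get((well, fld, acq_tag), {})
        missing = _REQUIRED[acq_tag] - set(channels)
        if missing:
            problems.append(f"{well}/f{fld}/{acq_tag}: missing {sorted(missing)}")
            return None
        imgs = {}
        for chan, path in channels.items():
            try:
                imgs[chan] = read_image(path, pixel_size)
            except Exception as exc:  # malformed TIFF reported with its path
                problems.append(f"{path}: {exc}")
                return None
        return Acquisition(imgs, well=well, field=fld)

    out = []
    if mode == "simultaneous":
        for (well, fld, acq_tag) in sorted(layout.groups):
            if acq_tag != "single":
                continue
            acq = build(well, fld, "single")
            if acq is not None:
                out.append(acq)
    else:
        keys = sorted({(w, f) for (w, f, a) in layout.groups if a in ("dna_pass", "rna_pass")})
        for well, fld in keys:
            dna = build(well, fld, "dna_pass")
            rna = build(well, fld, "rna_pass")
            if dna is not None and rna is not None:
                out.append((dna, rna))
    if problems:
        raise FileNotFoundError(
            "plate has gaps:\n  " + "\n  ".join(problems)
        )
    return out


def write_tables(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write all result tables: per-well partitions plus master tables.

    Cells and nuclei are partitioned one file per well; spots one file per
    well and per channel; a concatenated master table of each kind is also
    emitted. Column order is stable; missing distances serialize as ``NA``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, path: Path) -> None:
        df.to_csv(path, index=False, na_rep=NA_TOKEN, lineterminator="\n")
        written.append(path)

    for name, df in (
        ("nuclei", result.nuclei),
        ("cells", result.cells),
        ("alleles", result.alleles),
    ):
        emit(df, out / f"{name}.csv")
        for well, sub in df.groupby("well"):
            emit(sub, out / f"{name}_{well}.csv")

    emit(result.spots, out / "spots.csv")
    for (well, chan), sub in result.spots.groupby(["well", "channel"]):
        emit(sub, out / f"spots_{well}_{chan}.csv")

    summaries = result.summaries.copy()
    if "shell_histogram" in summaries:
        summaries["shell_histogram"] = summaries["shell_histogram"].apply(
            lambda h: "|".join(str(c) for c in h) if isinstance(h, list) else h
        )
    emit(summaries, out / "radial_summaries.csv")

    manifest = dict(result.manifest)
    manifest["tool_version"] = __version__
    manifest["outputs"] = [p.name for p in written]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    written.append(out / "manifest.json")
    return written


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_tables` (NA tokens -> NaN)."""
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
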