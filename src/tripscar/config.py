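"""Reporter model, pipeline parameters, sample sheet and configuration I/O.

The reporter is described in "remainder coordinates": position 0 is the first
base after the 3' barcode adapter (``TGATC``), i.e. the first base of the scar
region as it appears in an adapter-trimmed read. ``cut_offset`` and every
spacer ``expected_offset`` use this origin, and the simulator shares it, so
indel sizes computed from spacer shifts are internally consistent.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd
import yaml

from ._seq import find_all

log = logging.getLogger(__name__)

PCR_TYPES = {"ipcr": "iPCR", "indelpcr": "indelPCR"}

#: configuration keys from workflow-engine configs that are ignored on load
_WORKFLOW_KEYS = {"snakemake", "threads", "cores", "conda", "bowtie_index", "outdir"}


class ConfigError(ValueError):
    """A required configuration key is missing or malformed."""


class ValidationError(ValueError):
    """One or more invariant violations; message lists all of them."""


@dataclass
class ReporterSpec:
    """Structure of the barcoded DSB-repair reporter as read by the indel PCR.

    Attributes
    ----------
    wt_amplicon : str
        Wild-type scar-region sequence in remainder coordinates, from the
        first base after ``adapter_3p`` through (at least) the last spacer.
    adapter_5p, adapter_3p : str
        Constant arms flanking the reporter barcode.
    cut_offset : int
        Expected blunt Cas9 cut position in ``wt_amplicon`` coordinates.
    spacers : list[tuple[str, int]]
        Ordered ``(sequence, expected_offset)`` pairs; seven 6-mers whose
        positional shift in a read measures the indel size.
    recognition_seqs : dict[str, str]
        Named exact sequences whose presence names a read's call; must
        include ``"wt"``.
    """

    wt_amplicon: str
    adapter_5p: str
    adapter_3p: str
    cut_offset: int
    spacers: list[tuple[str, int]]
    recognition_seqs: dict[str, str]
    ipcr_read2_constant: str
    barcode_len_expected: int = 16
    barcode_len_range: tuple[int, int] = (15, 17)

    def validate(self) -> None:
        """Check every structural invariant; raise listing all violations."""
        problems: list[str] = []
        if not self.adapter_5p:
            problems.append("adapter_5p is empty")
        if not self.adapter_3p:
            problems.append("adapter_3p is empty")
        lo, hi = self.barcode_len_range
        if not (lo <= self.barcode_len_expected <= hi):
            problems.append(
                f"barcode_len_expected {self.barcode_len_expected} outside "
                f"barcode_len_range [{lo}, {hi}]"
            )
        offsets = [off for _, off in self.spacers]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            problems.append(f"spacer expected_offsets not strictly increasing: {offsets}")
        for seq, off in self.spacers:
            occ = find_all(self.wt_amplicon, seq)
            if len(occ) != 1:
                problems.append(
                    f"spacer {seq!r} occurs {len(occ)} times in wt_amplicon (expected 1)"
                )
            elif occ[0] != off:
                problems.append(
                    f"spacer {seq!r} found at {occ[0]}, expected_offset is {off}"
                )
        wt = self.recognition_seqs.get("wt")
        if wt is None:
            problems.append('recognition_seqs must include "wt"')
        else:
            pos = self.wt_amplicon.find(wt)
            if pos < 0:
                problems.append('recognition_seqs["wt"] is not a substring of wt_amplicon')
            elif not (pos <= self.cut_offset < pos + len(wt)):
                problems.append(
                    'recognition_seqs["wt"] does not span cut_offset '
                    f"({self.cut_offset})"
                )
        if problems:
            raise ValidationError("; ".join(problems))


@dataclass
class PipelineParams:
    """Thresholds used throughout the pipeline.

    Defaults follow the recommended filters: clustering radius 1 (Levenshtein
    distance < 2), >= 5 iPCR reads with average MAPQ > 10 at the primary
    location, >= 95% of reads at the primary and <= 2.5% at a secondary
    location, a pool of ~100,000 cells with ~6 barcodes each, a 50-cell
    abundance floor, a 0.01 DMSO indel-ratio floor, and adjusted p < 0.05 for
    inhibitor-based NHEJ classification.
    """

    max_barcode_dist: int = 1
    min_ipcr_reads: int = 5
    min_avg_mapq: float = 10.0
    min_primary_frac: float = 0.95
    max_secondary_frac: float = 0.025
    total_cells_assumed: int = 100_000
    mean_barcodes_per_cell: float = 6.0
    min_cells: float = 50.0
    adapter_max_mismatches: int = 1
    dmso_min_ratio: float = 0.01
    alpha_adj: float = 0.05

    def validate(self) -> None:
        problems: list[str] = []
        for name in ("min_primary_frac", "max_secondary_frac", "dmso_min_ratio", "alpha_adj"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name}={v} outside [0, 1]")
        if self.min_primary_frac + self.max_secondary_frac > 1.0 + 1e-12:
            problems.append("min_primary_frac + max_secondary_frac > 1")
        for name in (
            "max_barcode_dist",
            "min_ipcr_reads",
            "total_cells_assumed",
            "adapter_max_mismatches",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} is negative")
        for name in ("min_avg_mapq", "mean_barcodes_per_cell", "min_cells"):
            if getattr(self, name) < 0:
                problems.append(f"{name} is negative")
        if problems:
            raise ValidationError("; ".join(problems))


_REQUIRED_REPORTER_KEYS = (
    "wt_amplicon",
    "adapter_5p",
    "adapter_3p",
    "cut_offset",
    "spacers",
    "recognition_seqs",
    "ipcr_read2_constant",
)


def load_config(path: str | os.PathLike) -> tuple[ReporterSpec, PipelineParams]:
    """Load a flat YAML config with ``reporter:`` and ``params:`` sections.

    Unknown workflow-engine keys are ignored with a warning. Missing optional
    parameter keys take the documented defaults; missing required reporter
    keys raise :class:`ConfigError` naming the key.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "reporter" not in doc:
        raise ConfigError(f"{path}: missing required section 'reporter'")
    for key in set(doc) - {"reporter", "params"}:
        if key in _WORKFLOW_KEYS:
            log.warning("ignoring workflow-engine config key %r", key)
        else:
            log.warning("ignoring unknown config key %r", key)

    rep = dict(doc["reporter"])
    for key in _REQUIRED_REPORTER_KEYS:
        if key not in rep:
            raise ConfigError(f"{path}: missing required reporter key {key!r}")
    spacers = [(str(s), int(o)) for s, o in rep["spacers"]]
    spec = ReporterSpec(
        wt_amplicon=str(rep["wt_amplicon"]),
        adapter_5p=str(rep["adapter_5p"]),
        adapter_3p=str(rep["adapter_3p"]),
        cut_offset=int(rep["cut_offset"]),
        spacers=spacers,
        recognition_seqs={str(k): str(v) for k, v in rep["recognition_seqs"].items()},
        ipcr_read2_constant=str(rep["ipcr_read2_constant"]),
        barcode_len_expected=int(rep.get("barcode_len_expected", 16)),
        barcode_len_range=tuple(rep.get("barcode_len_range", (15, 17))),
    )
    par = dict(doc.get("params") or {})
    known = {f for f in PipelineParams.__dataclass_fields__}
    for key in set(par) - known:
        log.warning("ignoring unknown params key %r", key)
    params = PipelineParams(**{k: v for k, v in par.items() if k in known})
    spec.validate()
    params.validate()
    return spec, params


def write_config(spec: ReporterSpec, params: PipelineParams, path: str | os.PathLike) -> None:
    """Write a config that :func:`load_config` reads back identically."""
    doc = {
        "reporter": {
            "wt_amplicon": spec.wt_amplicon,
            "adapter_5p": spec.adapter_5p,
            "adapter_3p": spec.adapter_3p,
            "cut_offset": spec.cut_offset,
            "spacers": [[s, o] for s, o in spec.spacers],
            "recognition_seqs": dict(spec.recognition_seqs),
            "ipcr_read2_constant": spec.ipcr_read2_constant,
            "barcode_len_expected": spec.barcode_len_expected,
            "barcode_len_range": list(spec.barcode_len_range),
        },
        "params": asdict(params),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class SampleRow:
    sample_name: str
    file_location: str
    pcr_type: str  # normalized: "iPCR" | "indelPCR"
    guide_info: str = ""
    internal_index: Optional[str] = None
    condition: str = ""
    replicate: int = 1


@dataclass
class SampleSheet:
    rows: list[SampleRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def of_type(self, pcr_type: str) -> list[SampleRow]:
        want = PCR_TYPES[pcr_type.lower()]
        return [r for r in self.rows if r.pcr_type == want]


def load_sample_sheet(path: str | os.PathLike, check_files: bool = True) -> SampleSheet:
    """Load the tab-delimited sample sheet.

    Required columns: sample_name, file_location, pcr_type. Optional:
    guide_info, internal_index, condition, replicate. pcr_type is normalized
    case-insensitively; file_location is resolved relative to the sheet.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sample_name", "file_location", "pcr_type"):
        if col not in df.columns:
            raise ConfigError(f"{path}: sample sheet missing column {col!r}")
    dupes = df["sample_name"][df["sample_name"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate sample_name(s): {sorted(set(dupes))}")
    base = os.path.dirname(os.fspath(path))
    rows: list[SampleRow] = []
    for i, rec in df.iterrows():
        ptype = PCR_TYPES.get(rec["pcr_type"].strip().lower())
        if ptype is None:
            raise ValidationError(
                f"row {i} (sample {rec['sample_name']!r}): unknown pcr_type "
                f"{rec['pcr_type']!r}"
            )
        loc = rec["file_location"]
        if not os.path.isabs(loc):
            loc = os.path.normpath(os.path.join(base, loc))
        if check_files and not os.path.exists(loc):
            raise ValidationError(
                f"row {i} (sample {rec['sample_name']!r}): file not found: {loc}"
            )
        rows.append(
            SampleRow(
                sample_name=rec["sample_name"],
                file_location=loc,
                pcr_type=ptype,
                guide_info=rec.get("guide_info", ""),
                internal_index=rec.get("internal_index") or None,
                condition=rec.get("condition", ""),
                replicate=int(rec.get("replicate") or 1),
            )
        )
    return SampleSheet(rows)
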