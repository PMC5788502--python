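"""Sequence, annotation and aptamer-library I/O.

Transcripts are read from plain FASTA plus a sidecar TSV of region
annotations (5ʹ-UTR end, CDS end, cap status) so the FASTA stays standard.
Aptamer libraries are JSON; a small library of synthetic hairpin aptamers
(theophylline, tetracycline, eIF4G, β-catenin, NF-kB, VEGF, OPN) ships with
the package.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .fold import FoldError, dotbracket_to_pairs

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class RnaIOError(ValueError):
    """Raised for malformed inputs (sequences, annotations, libraries)."""


def normalize_rna(raw: str, *, context: str = "sequence") -> str:
    """Uppercase and map DNA T to RNA U; reject anything outside ACGUT."""
    seq = raw.strip().upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in "ACGU":
            raise RnaIOError(
                f"{context}: invalid character {ch!r} at position {pos} "
                "(expected A/C/G/T/U)"
            )
    return seq


def reverse_complement(sequence: str) -> str:
    """Watson–Crick reverse complement of an RNA string (A↔U, G↔C)."""
    seq = normalize_rna(sequence, context="reverse_complement input")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A target mRNA with 5ʹ-UTR/CDS annotation.

    ``utr5_end`` and ``cds_end`` are 0-based half-open region ends:
    the 5ʹ-UTR is ``[0, utr5_end)`` and the CDS is ``[utr5_end, cds_end)``.
    ``capped`` distinguishes an ordinary 5ʹ-capped mRNA from an "uncapped"
    reporter construct in which the ORF of interest sits downstream of a
    primary ORF (used for activation assays).
    """

    id: str
    sequence: str
    utr5_end: int
    cds_end: int
    capped: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise RnaIOError(f"transcript {self.id}: empty sequence")
        object.__setattr__(
            self, "sequence", normalize_rna(self.sequence, context=f"transcript {self.id}")
        )
        if not (0 <= self.utr5_end <= self.cds_end <= len(self.sequence)):
            raise RnaIOError(
                f"transcript {self.id}: require 0 <= utr5_end ({self.utr5_end}) "
                f"<= cds_end ({self.cds_end}) <= length ({len(self.sequence)})"
            )

    @property
    def utr5(self) -> tuple[int, int]:
        return (0, self.utr5_end)

    @property
    def cds(self) -> tuple[int, int]:
        return (self.utr5_end, self.cds_end)


@dataclass(frozen=True)
class Aptamer:
    """A ligand-binding RNA module.

    ``reference_structure`` is the dot-bracket structure the aptamer must
    keep inside a chimera; ``stem`` is the half-open interval of the 5ʹ stem
    strand (the strand a sequestration switch hybridizes against);
    ``role`` separates signal sensors from effector aptamers that recruit
    initiation machinery (eIF4G); ``binding_bonus`` is the free-energy-like
    stabilization (score units) conferred by ligand binding.
    """

    id: str
    ligand: str
    sequence: str
    reference_structure: str
    stem: tuple[int, int]
    role: str = "sensor"
    binding_bonus: float = 5.0

    def __post_init__(self):
        object.__setattr__(
            self, "sequence", normalize_rna(self.sequence, context=f"aptamer {self.id}")
        )
        object.__setattr__(self, "stem", tuple(self.stem))
        if self.role not in ("sensor", "effector"):
            raise RnaIOError(f"aptamer {self.id}: role must be sensor|effector")
        if self.binding_bonus < 0:
            raise RnaIOError(f"aptamer {self.id}: binding_bonus must be >= 0")
        if len(self.reference_structure) != len(self.sequence):
            raise RnaIOError(
                f"aptamer {self.id}: structure length {len(self.reference_structure)} "
                f"!= sequence length {len(self.sequence)}"
            )
        try:
            dotbracket_to_pairs(self.reference_structure)
        except FoldError as exc:
            raise RnaIOError(f"aptamer {self.id}: {exc}") from exc
        s, e = self.stem
        if not (0 <= s < e <= len(self.sequence)):
            raise RnaIOError(f"aptamer {self.id}: stem {self.stem} outside sequence")

    @property
    def reference_pairs(self) -> frozenset:
        return dotbracket_to_pairs(self.reference_structure)

    @property
    def stem_sequence(self) -> str:
        return self.sequence[self.stem[0] : self.stem[1]]


@dataclass
class AptamerLibrary:
    """Aptamers keyed by id."""

    entries: dict[str, Aptamer] = field(default_factory=dict)

    def add(self, aptamer: Aptamer) -> None:
        if aptamer.id in self.entries:
            raise RnaIOError(f"duplicate aptamer id {aptamer.id!r}")
        self.entries[aptamer.id] = aptamer

    def __getitem__(self, key: str) -> Aptamer:
        return self.entries[key]

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def by_ligand(self, ligand: str) -> list[Aptamer]:
        return [a for a in self.entries.values() if a.ligand == ligand]


def read_transcripts(fasta_path, annotation_path) -> list[Transcript]:
    """Read transcripts from FASTA plus a sidecar annotation TSV.

    The TSV must have columns ``id``, ``utr5_end``, ``cds_end``, ``capped``
    and one row per FASTA record; a record without an annotation row is a
    hard error naming the record.
    """
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"id": str})
    required = {"id", "utr5_end", "cds_end", "capped"}
    missing = required - set(ann.columns)
    if missing:
        raise RnaIOError(f"annotation file missing columns: {sorted(missing)}")
    ann = ann.set_index("id")
    if ann.index.duplicated().any():
        dups = ann.index[ann.index.duplicated()].tolist()
        raise RnaIOError(f"duplicate annotation rows for: {dups}")

    transcripts = []
    saw_dna_t = False
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in ann.index:
            raise RnaIOError(f"record {record.id!r} has no annotation row")
        raw = str(record.seq)
        if "T" in raw.upper():
            saw_dna_t = True
        row = ann.loc[record.id]
        transcripts.append(
            Transcript(
                id=record.id,
                sequence=raw,
                utr5_end=int(row["utr5_end"]),
                cds_end=int(row["cds_end"]),
                capped=_parse_bool(row["capped"]),
            )
        )
    if saw_dna_t:
        logger.info("DNA alphabet detected in %s; T normalized to U", fasta_path)
    return transcripts


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise RnaIOError(f"cannot parse boolean annotation value {value!r}")


def load_aptamer_library(json_path) -> AptamerLibrary:
    """Load an aptamer library from its documented JSON schema.

    Schema: ``{"entries": [{"id", "ligand", "sequence",
    "reference_structure", "stem": [start, end), "role", "binding_bonus"}]}``.
    Structures are validated as balanced dot-bracket on load.
    """
    with open(json_path) as fh:
        data = json.load(fh)
    return _library_from_dict(data, source=str(json_path))


def _library_from_dict(data: dict, source: str = "<dict>") -> AptamerLibrary:
    lib = AptamerLibrary()
    entries = data.get("entries", [])
    if not entries:
        logger.warning("aptamer library %s is empty", source)
    for entry in entries:
        apt = Aptamer(
            id=entry["id"],
            ligand=entry["ligand"],
            sequence=entry["sequence"],
            reference_structure=entry["reference_structure"],
            stem=tuple(entry["stem"]),
            role=entry.get("role", "sensor"),
            binding_bonus=float(entry.get("binding_bonus", 5.0)),
        )
        lib.add(apt)
    return lib


def packaged_aptamer_library() -> AptamerLibrary:
    """The library of synthetic hairpin aptamers shipped with the package.

    These entries are synthetic reconstructions of the described device
    architecture (a stem–loop with an annotated 5ʹ stem strand), not
    experimentally selected aptamer sequences; see the JSON file notes.
    """
    with resources.files("riboconnect.data").joinpath("aptamers.json").open() as fh:
        data = json.load(fh)
    return _library_from_dict(data, source="packaged aptamers.json")


def write_design_report(designs: Iterable, path) -> None:
    """Write a TSV design report plus a companion FASTA of device sequences.

    One row per design: id, topology, target window, antisense, the three
    selection scores, the composite and the pass flag.  Raises if any design
    has not been scored.  The FASTA lands next to the TSV with suffix
    ``.fasta``.
    """
    path = Path(path)
    rows = []
    fasta_lines = []
    for d in designs:
        if d.scores is None:
            raise RnaIOError(f"design {d.id} has not been scored")
        rows.append(
            {
                "id": d.id,
                "topology": d.topology,
                "target_id": d.target_id,
                "window_start": d.window[0],
                "window_end": d.window[1],
                "region": d.region,
                "antisense": d.antisense,
                "exposedness": round(d.scores.exposedness, 6),
                "preservation": round(d.scores.preservation, 6),
                "position_prior": round(d.scores.position_prior, 6),
                "composite": round(d.scores.composite, 6),
                "passed": d.scores.passed,
                "notes": ";".join(getattr(d, "notes", ()) or ()),
            }
        )
        fasta_lines.append(f">{d.id}\n{d.full_sequence}")
    columns = [
        "id", "topology", "target_id", "window_start", "window_end", "region",
        "antisense", "exposedness", "preservation", "position_prior",
        "composite", "passed", "notes",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    path.with_suffix(".fasta").write_text("\n".join(fasta_lines) + ("\n" if fasta_lines else ""))


def read_device_fasta(path) -> dict[str, str]:
    """Read a device FASTA back as an id → sequence map (round-trip aid)."""
    return {
        rec.id: normalize_rna(str(rec.seq), context=f"device {rec.id}")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def packaged_device_params() -> dict:
    """Calibration parameters of the packaged reference devices (JSON)."""
    with resources.files("riboconnect.data").joinpath("device_params.json").open() as fh:
        return json.load(fh)
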