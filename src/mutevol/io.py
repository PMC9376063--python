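"""Readers and writers for the formats the pipeline exchanges.

Supported formats:

* FASTA reference genomes (via Biopython).
* A minimal VCF dialect for mutation calls: the eight mandatory columns
  ``CHROM POS ID REF ALT QUAL FILTER INFO``; the line identifier is carried in
  the INFO key ``LINE`` (or an extra trailing ``LINE`` column).  Unknown INFO
  keys are preserved verbatim.
* Tab-separated tables with a header row for every tabular artifact.

Coordinates are 1-based, closed intervals, VCF-style, everywhere.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("mutevol")

VALID_BASES = frozenset("ACGT")
MUTATION_CLASSES = ("SNM", "SIM", "SV")
SV_TYPES = ("DEL", "DUP", "INV", "INS")

#: small indels are at most this many bases; anything longer is a SV
MAX_SIM_LEN = 4


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def setup_logging(level: int = logging.INFO) -> None:
    """Log one line per pipeline stage to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def log_stage(stage: str, n_in: int, n_out: int) -> None:
    logger.info("%s: %d in, %d out", stage, n_in, n_out)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


class ReferenceGenome:
    """Ordered mapping of sequence name to uppercase nucleotide string.

    Non-ACGT bases (e.g. IUPAC ambiguity codes from masked assemblies) are
    tolerated but recorded in :attr:`ambiguous_sites`; downstream context
    counting skips them.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise FormatError("reference genome has no sequences")
        self.sequences: dict[str, str] = {}
        self.ambiguous_sites: dict[str, frozenset[int]] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise FormatError(f"sequence {name!r} is empty")
            self.sequences[name] = seq
            bad = frozenset(
                i for i, b in enumerate(seq) if b not in VALID_BASES
            )
            if bad:
                self.ambiguous_sites[name] = bad

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReferenceGenome)
            and self.sequences == other.sequences
        )


def read_fasta(path) -> ReferenceGenome:
    """Read a FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased (soft-masked lowercase runs included); order of
    records is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq)
    except Exception as exc:  # Biopython raises ValueError subclasses
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Mutation calls
# ---------------------------------------------------------------------------


def classify_alleles(ref: str, alt: str) -> str:
    """Infer the mutation class from REF/ALT allele lengths.

    Equal-length single bases are SNMs; indels of at most ``MAX_SIM_LEN``
    bases are SIMs; anything else is a SV.
    """
    if len(ref) == 1 and len(alt) == 1:
        return "SNM"
    diff = abs(len(ref) - len(alt))
    if 1 <= diff <= MAX_SIM_LEN:
        return "SIM"
    return "SV"


@dataclass
class MutationCall:
    """One variant call in one MA line."""

    line_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    mclass: str
    depth: Optional[int] = None
    qual: Optional[float] = None
    sv_type: Optional[str] = None
    sv_start: Optional[int] = None
    sv_end: Optional[int] = None
    source: Optional[str] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.mclass not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mclass!r}")
        if self.mclass == "SNM":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(
                    f"SNM requires single distinct bases, got "
                    f"{self.ref!r}>{self.alt!r}"
                )
        elif self.mclass == "SIM":
            diff = abs(len(self.ref) - len(self.alt))
            if not 1 <= diff <= MAX_SIM_LEN:
                raise ValueError(
                    f"SIM requires a 1-{MAX_SIM_LEN} bp length difference, "
                    f"got {diff}"
                )
        else:  # SV
            if self.sv_type is not None and self.sv_type not in SV_TYPES:
                raise ValueError(f"unknown sv_type {self.sv_type!r}")
            if (
                self.sv_start is not None
                and self.sv_end is not None
                and self.sv_start > self.sv_end
            ):
                raise ValueError("sv_start must be <= sv_end")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def key(self) -> tuple:
        """Identity key used for ancestral subtraction / consensus grouping."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def interval(self) -> tuple[int, int]:
        """Closed 1-based interval of a SV (falls back to the point locus)."""
        if self.sv_start is not None and self.sv_end is not None:
            return (self.sv_start, self.sv_end)
        return (self.pos, self.pos)


_VCF_COLUMNS = ["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]


def _parse_info(text: str) -> dict:
    info: dict = {}
    if text in (".", ""):
        return info
    for item in text.split(";"):
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            info[key] = value
        else:
            info[item] = True
    return info


def _format_info(info: Mapping) -> str:
    if not info:
        return "."
    parts = []
    for key, value in info.items():
        if value is True:
            parts.append(str(key))
        else:
            parts.append(f"{key}={value}")
    return ";".join(parts)


def read_calls(path) -> list[MutationCall]:
    """Read mutation calls from a minimal-VCF file.

    The mutation class is inferred from allele lengths unless the INFO field
    carries an explicit ``SVTYPE`` key, which forces class SV.
    """
    path = Path(path)
    calls: list[MutationCall] = []
    header: Optional[list[str]] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                missing = [c for c in _VCF_COLUMNS if c not in header]
                if missing:
                    raise FormatError(
                        f"{path}:{lineno}: missing mandatory columns {missing}"
                    )
                continue
            if header is None:
                raise FormatError(f"{path}: no #CHROM header line before data")
            fields = line.split("\t")
            if len(fields) < len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            try:
                pos = int(row["POS"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer POS {row['POS']!r}"
                ) from exc
            info = _parse_info(row["INFO"])
            line_id = row.get("LINE") or info.get("LINE")
            if not line_id:
                raise FormatError(
                    f"{path}:{lineno}: no line identifier (LINE column or "
                    "INFO key LINE)"
                )
            ref, alt = row["REF"], row["ALT"]
            if "SVTYPE" in info:
                mclass = "SV"
            else:
                mclass = classify_alleles(ref, alt)
            depth = int(info["DP"]) if "DP" in info else None
            qual = None if row["QUAL"] in (".", "") else float(row["QUAL"])
            sv_type = info.get("SVTYPE")
            sv_start = int(info["SVSTART"]) if "SVSTART" in info else None
            sv_end = int(info["END"]) if "END" in info else None
            if mclass == "SV" and sv_start is None:
                sv_start = pos
            extra = {
                k: v
                for k, v in info.items()
                if k not in ("LINE", "DP", "SVTYPE", "SVSTART", "END", "SOURCE")
            }
            calls.append(
                MutationCall(
                    line_id=str(line_id),
                    chrom=row["CHROM"],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    mclass=mclass,
                    depth=depth,
                    qual=qual,
                    sv_type=sv_type,
                    sv_start=sv_start,
                    sv_end=sv_end,
                    source=info.get("SOURCE"),
                    info=extra,
                )
            )
    return calls


def write_calls(calls: Iterable[MutationCall], path) -> None:
    """Write calls as minimal VCF (round-trips with :func:`read_calls`)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#" + "\t".join(_VCF_COLUMNS) + "\n")
        for call in calls:
            info = dict(call.info)
            info["LINE"] = call.line_id
            if call.depth is not None:
                info["DP"] = call.depth
            if call.sv_type is not None:
                info["SVTYPE"] = call.sv_type
            if call.sv_start is not None:
                info["SVSTART"] = call.sv_start
            if call.sv_end is not None:
                info["END"] = call.sv_end
            if call.source is not None:
                info["SOURCE"] = call.source
            qual = "." if call.qual is None else f"{call.qual:g}"
            fh.write(
                "\t".join(
                    [
                        call.chrom,
                        str(call.pos),
                        ".",
                        call.ref,
                        call.alt,
                        qual,
                        "PASS",
                        _format_info(info),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Generic tables and configuration
# ---------------------------------------------------------------------------


def write_table(records, path, columns: Optional[Sequence[str]] = None) -> None:
    """Write records (DataFrame, or sequence of dicts/dataclasses) as TSV.

    Floats are written at full precision so that write/read round-trips are
    lossless.  ``columns`` supplies the schema when ``records`` is empty.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                rows.append(
                    {k: getattr(rec, k) for k in rec.__dataclass_fields__}
                )
            else:
                rows.append(dict(rec))
        frame = pd.DataFrame(rows, columns=columns if not rows else None)
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    """Load a nested key-value configuration file (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping at top level")
    return cfg
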