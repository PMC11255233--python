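"""Combinatorial peptide-library design.

The screen's library has three groups plus controls:

1. *scan* — every overlapping k-mer window (offset 1) of a set of source
   proteins, so adjacent peptides differ by one residue;
2. *substitution* — for each parent peptide, every single-residue variant
   (19 alternatives at each position), optionally plus the parent itself;
3. *random* — novel k-mers built by recombining fragments of the scan group.

Blank spots and the haemagglutinin (HA) epitope are added as controls.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import (
    AMINO_ACIDS,
    BLANK_ID,
    HA_EPITOPE,
    PARENT_PEPTIDES,
    validate_sequence,
)

GROUPS = ("scan", "substitution", "random", "control", "blank")

LIBRARY_COLUMNS = [
    "peptide_id",
    "sequence",
    "group",
    "source_protein",
    "start",
    "parent",
    "sub_pos",
    "sub_from",
    "sub_to",
    "replicates",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A source protein: identifier plus a canonical amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, context=f"protein {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideEntry:
    """One library member with full provenance.

    ``start`` and ``sub_pos`` are 1-based residue positions.
    """

    peptide_id: str
    sequence: str
    group: str
    source_protein: str | None = None
    start: int | None = None
    parent: str | None = None
    sub_pos: int | None = None
    sub_from: str | None = None
    sub_to: str | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "blank":
            if self.sequence:
                raise ValueError("blank entries carry an empty sequence")
        else:
            validate_sequence(self.sequence, context=f"peptide {self.peptide_id!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class LibraryConfig:
    """Parameters of the chip's library design.

    Defaults follow the main screen: 15-mer windows at offset 1, replicate
    counts 5/3/2 for the scan/substitution/random groups, 9818 random
    recombinants, and parents included among the substitution entries.
    """

    k: int = 15
    step: int = 1
    replicates_scan: int = 5
    replicates_substitution: int = 3
    replicates_random: int = 2
    replicates_control: int = 5
    n_random: int = 9818
    include_parents: bool = True
    n_blank: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.step < 1:
            raise ValueError("k and step must be >= 1")
        for r in (
            self.replicates_scan,
            self.replicates_substitution,
            self.replicates_random,
            self.replicates_control,
        ):
            if r < 1:
                raise ValueError("replicate counts must be >= 1")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file of proteins."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def tile_protein(
    protein: ProteinRecord, k: int = 15, step: int = 1, replicates: int = 5
) -> list[PeptideEntry]:
    """All overlapping k-mer windows of *protein* at the given offset.

    Windows are emitted in ascending start order with 1-based start
    coordinates; for step 1 there are ``length - k + 1`` of them.
    """
    if protein.length < k:
        raise ValueError(
            f"protein {protein.id!r} (length {protein.length}) is shorter than k={k}"
        )
    entries = []
    for start0 in range(0, protein.length - k + 1, step):
        start = start0 + 1
        entries.append(
            PeptideEntry(
                peptide_id=f"{protein.id}_w{start:04d}",
                sequence=protein.sequence[start0 : start0 + k],
                group="scan",
                source_protein=protein.id,
                start=start,
                replicates=replicates,
            )
        )
    return entries


def substitution_scan(
    parent: str,
    include_parent: bool = False,
    parent_id: str | None = None,
    replicates: int = 3,
) -> list[PeptideEntry]:
    """Every single-residue substitution variant of *parent*.

    Each of the ``len(parent)`` positions is replaced in turn by the 19
    other biogenic amino acids, giving ``19 * len(parent)`` variants, plus
    the parent itself when *include_parent* is set.
    """
    validate_sequence(parent, context="parent")
    pid = parent_id or parent
    entries: list[PeptideEntry] = []
    if include_parent:
        entries.append(
            PeptideEntry(
                peptide_id=f"{pid}_parent",
                sequence=parent,
                group="substitution",
                parent=parent,
                replicates=replicates,
            )
        )
    for pos0, original in enumerate(parent):
        for aa in AMINO_ACIDS:
            if aa == original:
                continue
            variant = parent[:pos0] + aa + parent[pos0 + 1 :]
            entries.append(
                PeptideEntry(
                    peptide_id=f"{pid}_s{pos0 + 1:02d}{original}{aa}",
                    sequence=variant,
                    group="substitution",
                    parent=parent,
                    sub_pos=pos0 + 1,
                    sub_from=original,
                    sub_to=aa,
                    replicates=replicates,
                )
            )
    return entries


def recombine_fragments(
    pool: Sequence[str],
    n: int,
    length: int = 15,
    seed: int = 0,
    replicates: int = 2,
    max_attempts_per_target: int = 200,
) -> list[PeptideEntry]:
    """Build *n* unique novel k-mers by recombining fragments of *pool*.

    Construction rule: draw two pool peptides uniformly, pick a split point,
    and join the prefix of the first to the suffix of the second, cropped to
    exactly *length* residues. Results are rejected when they duplicate a
    pool member or a previously accepted recombinant, so the output is
    disjoint from the pool. Deterministic for a fixed (pool, n, length, seed).
    """
    if not pool:
        raise ValueError("fragment pool must be non-empty")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    pool_arr = list(pool)
    forbidden = set(pool_arr)
    seen: set[str] = set()
    out: list[str] = []
    budget = max(1, n) * max_attempts_per_target
    attempts = 0
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"recombination attempt budget exhausted: achieved {len(out)} of {n} "
                f"unique sequences after {attempts} attempts"
            )
        attempts += 1
        i, j = rng.integers(0, len(pool_arr), size=2)
        a, b = pool_arr[i], pool_arr[j]
        t = int(rng.integers(1, length))
        seq = (a[:t] + b[t:])[:length]
        if len(seq) < length:
            continue
        if seq in forbidden or seq in seen:
            continue
        seen.add(seq)
        out.append(seq)
    return [
        PeptideEntry(
            peptide_id=f"RND_{i + 1:05d}",
            sequence=seq,
            group="random",
            replicates=replicates,
        )
        for i, seq in enumerate(out)
    ]


def assemble_library(
    config: LibraryConfig,
    proteins: Sequence[ProteinRecord] = (),
    parents: Sequence[str] = PARENT_PEPTIDES,
) -> tuple[list[PeptideEntry], dict]:
    """Assemble the full chip library: three groups plus controls and blanks.

    Returns the entry list and an assembly report with group sizes, the
    total replicate-spot count, and cross-group duplicate sequences.
    Duplicates are kept (every entry stays addressable by its own id) and
    reported rather than silently dropped.
    """
    entries: list[PeptideEntry] = []
    for protein in proteins:
        entries.extend(
            tile_protein(protein, config.k, config.step, replicates=config.replicates_scan)
        )
    for parent in parents:
        entries.extend(
            substitution_scan(
                parent,
                include_parent=config.include_parents,
                replicates=config.replicates_substitution,
            )
        )
    scan_seqs = [e.sequence for e in entries if e.group == "scan"]
    if config.n_random > 0:
        if not scan_seqs:
            raise ValueError("random group requested but the scan pool is empty")
        entries.extend(
            recombine_fragments(
                scan_seqs,
                config.n_random,
                length=config.k,
                seed=config.seed,
                replicates=config.replicates_random,
            )
        )
    entries.append(
        PeptideEntry(
            peptide_id="HA_CTRL",
            sequence=HA_EPITOPE,
            group="control",
            replicates=config.replicates_control,
        )
    )
    for b in range(config.n_blank):
        entries.append(
            PeptideEntry(peptide_id=f"{BLANK_ID}_{b + 1:04d}", sequence="", group="blank")
        )

    ids = Counter(e.peptide_id for e in entries)
    dup_ids = sorted(i for i, c in ids.items() if c > 1)
    if dup_ids:
        raise ValueError(f"duplicate peptide ids in library: {dup_ids[:10]}")

    seq_owners: dict[str, list[str]] = {}
    for e in entries:
        if e.group in ("blank",):
            continue
        seq_owners.setdefault(e.sequence, []).append(e.peptide_id)
    duplicates = {s: owners for s, owners in seq_owners.items() if len(owners) > 1}

    group_sizes = Counter(e.group for e in entries)
    report = {
        "group_sizes": dict(group_sizes),
        "n_unique_sequences": len(seq_owners),
        "n_duplicate_sequences": len(duplicates),
        "duplicate_sequences": {s: owners for s, owners in sorted(duplicates.items())},
        "total_replicate_spots": int(sum(e.replicates for e in entries)),
    }
    return entries, report


def library_to_frame(entries: Iterable[PeptideEntry]) -> pd.DataFrame:
    """Flatten entries into the library table (one row per peptide)."""
    rows = [dataclasses.asdict(e) for e in entries]
    df = pd.DataFrame(rows, columns=LIBRARY_COLUMNS)
    for col in ("start", "sub_pos"):
        df[col] = df[col].astype("Int64")
    return df


def frame_to_library(df: pd.DataFrame) -> list[PeptideEntry]:
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            PeptideEntry(
                peptide_id=str(row.peptide_id),
                sequence="" if pd.isna(row.sequence) else str(row.sequence),
                group=str(row.group),
                source_protein=None if pd.isna(row.source_protein) else str(row.source_protein),
                start=None if pd.isna(row.start) else int(row.start),
                parent=None if pd.isna(row.parent) else str(row.parent),
                sub_pos=None if pd.isna(row.sub_pos) else int(row.sub_pos),
                sub_from=None if pd.isna(row.sub_from) else str(row.sub_from),
                sub_to=None if pd.isna(row.sub_to) else str(row.sub_to),
                replicates=int(row.replicates),
            )
        )
    return entries


def write_library(entries: Iterable[PeptideEntry], path: str | Path, header_comment: str | None = None) -> None:
    df = library_to_frame(entries)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_library(path: str | Path) -> list[PeptideEntry]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=True, na_values=[""])
    return frame_to_library(df)
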