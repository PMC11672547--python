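"""File I/O: FASTA alignments, affinity tables, scaffold JSON, logo exports.

All on-disk formats are plain text: FASTA for sequences, TSV with header
``id<TAB>sequence<TAB>ki`` for affinity tables, JSON for scaffolds and logo
bundles. Ki values are stored in molar internally; table readers take an
explicit unit so the mixed nM/uM usage common in the literature never leaks
into computation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq_core import (MSA, AffinityRecord, Alphabet, FrequencyMatrix,
                       Scaffold, information_content)

logger = logging.getLogger("pepevo")

#: Ki unit -> multiplier to molar. Both the micro sign and "uM" are accepted.
KI_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "nM": 1e-9}


def read_fasta(path: str | Path, scaffold: Scaffold,
               alphabet: Alphabet | None = None,
               permissive: bool = False) -> MSA:
    """Read a FASTA file of scaffold-conformant peptides into an MSA.

    In strict mode (default) any record that violates the scaffold length,
    a fixed position, or the alphabet raises a ValueError naming the record
    and position. With ``permissive=True`` offending records are dropped with
    a logged warning and count instead.
    """
    alphabet = alphabet or Alphabet()
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ids: list[str] = []
    seqs: list[str] = []
    dropped = 0
    for rec in records:
        seq = str(rec.seq).upper()
        try:
            if any(s not in alphabet.symbols for s in seq):
                bad = next(i for i, s in enumerate(seq, 1)
                           if s not in alphabet.symbols)
                raise ValueError(
                    f"record {rec.id!r}: invalid symbol {seq[bad - 1]!r} "
                    f"at position {bad}")
            try:
                scaffold.check(seq)
            except ValueError as exc:
                raise ValueError(f"record {rec.id!r}: {exc}") from exc
        except ValueError:
            if permissive:
                dropped += 1
                continue
            raise
        ids.append(rec.id)
        seqs.append(seq)
    if dropped:
        logger.warning("read_fasta: dropped %d non-conformant record(s) from %s",
                       dropped, path)
    if not ids:
        raise ValueError(f"all records in {path} were non-conformant")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    return MSA.from_sequences(ids, seqs, scaffold, alphabet)


def write_fasta(msa: MSA, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=seq_id, description="")
               for seq_id, seq in zip(msa.ids, msa.sequences())]
    SeqIO.write(records, str(path), "fasta")


def write_sequences_fasta(ids, sequences, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(ids, sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_affinity_table(path: str | Path, scaffold: Scaffold,
                        ki_unit: str = "nM",
                        alphabet: Alphabet | None = None,
                        family: str = "") -> list[AffinityRecord]:
    """Read a delimited table with columns id, sequence, ki into records.

    Ki values are converted from ``ki_unit`` to molar. Every sequence is
    validated against the scaffold; malformed or non-positive Ki rows raise.
    """
    if ki_unit not in KI_UNITS:
        raise ValueError(f"unknown Ki unit {ki_unit!r}; use one of {list(KI_UNITS)}")
    alphabet = alphabet or Alphabet()
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "sequence", "ki"):
        if col not in df.columns:
            raise ValueError(f"affinity table missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        ki = float(row["ki"])
        if not np.isfinite(ki) or ki <= 0:
            raise ValueError(f"record {row['id']!r}: Ki must be positive, got {row['ki']}")
        seq = str(row["sequence"]).strip().upper()
        alphabet.encode(seq)  # validates symbols
        try:
            scaffold.check(seq)
        except ValueError as exc:
            raise ValueError(f"record {row['id']!r}: {exc}") from exc
        records.append(AffinityRecord(id=str(row["id"]), sequence=seq,
                                      ki=ki * KI_UNITS[ki_unit], family=family))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in affinity table")
    return records


def write_affinity_table(records, path: str | Path, ki_unit: str = "nM") -> None:
    mult = KI_UNITS[ki_unit]
    df = pd.DataFrame({"id": [r.id for r in records],
                       "sequence": [r.sequence for r in records],
                       "ki": [r.ki / mult for r in records]})
    df.to_csv(path, sep="\t", index=False)


def write_scaffold(scaffold: Scaffold, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scaffold.to_dict(), indent=2))


def read_scaffold(path: str | Path) -> Scaffold:
    return Scaffold.from_dict(json.loads(Path(path).read_text()))


def write_frequency_tsv(fm: FrequencyMatrix, path: str | Path) -> None:
    """Frequency matrix as TSV: L rows x q columns, header = alphabet."""
    df = pd.DataFrame(fm.freqs, columns=list(fm.alphabet.symbols))
    df.insert(0, "position", np.arange(1, fm.L + 1))
    df.to_csv(path, sep="\t", index=False)


def write_logo_json(fm: FrequencyMatrix, scaffold: Scaffold,
                    path: str | Path) -> None:
    """Logo bundle: frequencies, information content (bits), alphabet, scaffold."""
    bundle = {"freqs": fm.freqs.tolist(),
              "ic_bits": information_content(fm).tolist(),
              "alphabet": fm.alphabet.symbols,
              "pseudocount": fm.pseudocount,
              "n_sequences": fm.n_sequences,
              "scaffold": scaffold.to_dict()}
    Path(path).write_text(json.dumps(bundle, indent=2))
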