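"""End-motif profile extraction from aligned cfDNA fragments.

A cfDNA fragment has two 5' ends: the Watson-strand end at the fragment's
left coordinate and the Crick-strand end at its right coordinate. The end
motif is the 4-mer of *reference* sequence starting at each 5' end (for the
Crick end, read 5'->3' on the minus strand, i.e. the reverse complement of
the reference window ending at the right coordinate). Counting both ends
over all retained fragments and normalising gives a 256-dimensional
end-motif (EM) profile per sample, ordered lexicographically AAAA..TTTT.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
#: the 256 4-mers in lexicographic order (A < C < G < T)
MOTIFS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=4)
)
MOTIF_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOTIFS)}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_MAX_INSERT = 600
DEFAULT_MIN_MAPQ = 20


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Fragment:
    """A sequenced cfDNA fragment span, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"fragment start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class EndMotifProfile:
    """Per-sample counts and frequencies over the 256 end motifs."""

    sample_id: str
    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (256,):
            raise ValueError("counts must have shape (256,)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty profile: no motif counts")
        return self.counts / total

    def frequency(self, motif: str) -> float:
        return float(self.frequencies[MOTIF_INDEX[motif]])


@dataclass
class ProfileMatrix:
    """Samples x 256 end-motif frequency matrix with optional binary labels."""

    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 256:
            raise ValueError("profile matrix must be n_samples x 256")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels length mismatch")
            if not set(np.unique(self.labels)) <= {0, 1}:
                raise ValueError("labels must be binary {0, 1}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=list(MOTIFS))
        df.index.name = "sample_id"
        if self.labels is not None:
            df["label"] = self.labels
        return df


def load_fragments(
    path: str | Path,
    max_insert: int = DEFAULT_MAX_INSERT,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[Fragment]:
    """Load fragment spans from a BED3 file or a coordinate-sorted BAM.

    BAM mode keeps only proper pairs mapped to the same chromosome with
    correct orientation, skipping duplicates, secondary/supplementary
    records and reads below ``min_mapq``; each template is counted once
    (from the leftmost mate). Spans longer than ``max_insert`` are dropped
    in both modes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.suffix.lower() == ".bam":
        frags = list(_iter_bam(path, min_mapq))
    else:
        frags = list(_iter_bed(path))
    kept = [f for f in frags if f.length <= max_insert]
    dropped = len(frags) - len(kept)
    if dropped:
        logger.info("dropped %d fragments longer than %d bp", dropped, max_insert)
    if not kept:
        warnings.warn(f"no fragments retained from {path}", stacklevel=2)
    return kept


def _iter_bed(path: Path) -> Iterator[Fragment]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            yield Fragment(chrom, start, end)


def _iter_bam(path: Path, min_mapq: int) -> Iterator[Fragment]:
    import pysam

    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or not read.is_proper_pair
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.is_read2  # count each template once
                or read.mapping_quality < min_mapq
            ):
                continue
            if read.reference_id != read.next_reference_id:
                continue
            tlen = read.template_length
            if tlen <= 0:  # read1 is the rightmost mate; template seen from mate
                continue
            yield Fragment(read.reference_name, read.reference_start,
                           read.reference_start + tlen)


def end_motifs_of_fragment(frag: Fragment, ref) -> tuple[str, str] | None:
    """The two 5'-end 4-mers of a fragment from the reference.

    ``ref`` is a mapping of chromosome name to sequence (e.g. a
    ``pyfaidx.Fasta`` or a plain dict of strings). Returns ``None`` when a
    4-mer window falls off the chromosome or contains a non-ACGT base
    (callers count such skips).
    """
    try:
        chrom = ref[frag.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {frag.chrom!r} not in reference") from exc
    chrom_len = len(chrom)
    if frag.start + 4 > chrom_len or frag.end - 4 < 0 or frag.end > chrom_len:
        warnings.warn(
            f"4-mer window off chromosome for fragment "
            f"{frag.chrom}:{frag.start}-{frag.end}; skipped",
            stacklevel=2,
        )
        return None
    watson = str(chrom[frag.start : frag.start + 4]).upper()
    right = str(chrom[frag.end - 4 : frag.end]).upper()
    crick = revcomp(right)
    if any(b not in BASES for b in watson + crick):
        return None
    return watson, crick


def build_profile(
    fragments: Iterable[Fragment], ref, sample_id: str
) -> EndMotifProfile:
    """Count both 5'-end motifs of every fragment into a 256-bin profile."""
    counts = np.zeros(256, dtype=np.int64)
    n_skipped = 0
    n_used = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for frag in fragments:
            pair = end_motifs_of_fragment(frag, ref)
            if pair is None:
                n_skipped += 1
                continue
            watson, crick = pair
            counts[MOTIF_INDEX[watson]] += 1
            counts[MOTIF_INDEX[crick]] += 1
            n_used += 1
    if n_used == 0:
        raise ValueError(f"empty profile for sample {sample_id!r}: "
                         "no fragments survived extraction")
    if n_skipped:
        logger.info("sample %s: skipped %d fragments (off-chromosome or "
                    "ambiguous reference bases)", sample_id, n_skipped)
    return EndMotifProfile(sample_id=sample_id, counts=counts, n_skipped=n_skipped)


def profiles_to_matrix(
    profiles: Sequence[EndMotifProfile], labels: Sequence[int] | None = None
) -> ProfileMatrix:
    values = np.stack([p.frequencies for p in profiles])
    return ProfileMatrix(
        sample_ids=[p.sample_id for p in profiles],
        values=values,
        labels=None if labels is None else np.asarray(labels),
    )


def read_profile_matrix(path: str | Path) -> ProfileMatrix:
    """Read a profile TSV (sample_id, 256 motif columns, optional label).

    Rows whose frequencies do not sum to 1 within 1e-6 are renormalised
    with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [m for m in MOTIFS if m not in df.columns]
    if missing:
        raise ValueError(f"profile matrix {path} missing motif column(s): "
                         f"{', '.join(missing[:5])}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample_id {dup!r} in {path}")
    values = df[list(MOTIFS)].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"non-numeric or non-finite cell in {path}")
    row_sums = values.sum(axis=1)
    off = np.abs(row_sums - 1.0) > 1e-6
    if off.any():
        warnings.warn(
            f"{int(off.sum())} row(s) in {path} do not sum to 1; renormalising",
            stacklevel=2,
        )
        values[off] = values[off] / row_sums[off, None]
    labels = None
    if "label" in df.columns:
        labels = df["label"].to_numpy(dtype=int)
    return ProfileMatrix(
        sample_ids=[str(s) for s in df.index], values=values, labels=labels
    )


def write_profile_matrix(pm: ProfileMatrix, path: str | Path) -> None:
    """Write a profile matrix as TSV with full float precision."""
    pm.to_frame().to_csv(path, sep="\t", float_format="%.17g")
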