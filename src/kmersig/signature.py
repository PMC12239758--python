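"""Streaming k-mer signature extraction from FASTQ files.

A sample's *signature* is the vector of relative frequencies of all 4^k
k-mers over {A, C, G, T}, counted on the forward strand with a stride-1
sliding window over every read. Counting is exact integer accumulation
with a single final division, so signatures are bitwise identical across
read orderings, batch boundaries and degrees of parallelism. Raw reads are
consumed as-is: no quality trimming, no host depletion, no taxonomic
classification — the whole point of the approach is that none of that is
needed for the downstream diagnostic models.

Windows containing any symbol outside ACGT (N calls, IUPAC codes) are
skipped and tallied in ``n_skipped_windows`` rather than being forced into
a fifth symbol; this keeps the feature universe at exactly 4^k columns.
"""

from __future__ import annotations

import csv
import gzip
import io
import itertools
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import (
    EmptySampleError,
    FastqFormatError,
    MetadataError,
    ParameterError,
    TableFormatError,
)

ALPHABET = ("A", "C", "G", "T")

MAX_K = 12  # 4^12 ≈ 16.7M columns; beyond this dense counting is unreasonable

# byte -> 2-bit base code; 255 marks any symbol outside ACGT (case-sensitive
# by construction: the read stream upper-cases before counting)
_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _BASE_CODES[ord(_b)] = _i

DEFAULT_BATCH_LINES = 128  # 32 FASTQ records per read cycle


@dataclass(frozen=True)
class KmerSpec:
    """The feature universe for a chosen k: all 4^k k-mers in lexicographic order."""

    k: int
    vocabulary: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    @property
    def n_features(self) -> int:
        return len(self.vocabulary)

    @property
    def powers(self) -> np.ndarray:
        """Place values 4^(k-1) .. 4^0 used to map a window of base codes to a column."""
        return 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)


@dataclass
class SampleSignature:
    """One sample's normalized k-mer frequency vector plus counting provenance."""

    sample_id: str
    k: int
    counts_total: int
    frequencies: np.ndarray
    n_reads: int
    n_skipped_windows: int


@dataclass
class FeatureTable:
    """samples × features matrix with labels; the contract between extraction and modelling."""

    sample_ids: list[str]
    feature_names: list[str]
    matrix: np.ndarray
    labels: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.sample_ids), len(self.feature_names)):
            raise MetadataError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if len(self.labels) != len(self.sample_ids):
            raise MetadataError("labels do not align with sample_ids")
        if np.isnan(self.matrix).any():
            raise MetadataError("feature table contains missing values")


def iter_kmers(k: int) -> Iterator[str]:
    """Lazily yield all 4^k k-mers in lexicographic order (A < C < G < T)."""
    for tup in itertools.product(ALPHABET, repeat=k):
        yield "".join(tup)


def enumerate_kmers(k: int) -> KmerSpec:
    """Build the ordered k-mer vocabulary and its column-index map.

    Parameters
    ----------
    k : int
        Word length; must satisfy 1 <= k <= 12. The diagnostic pipeline
        uses k = 3, 5, 7 (64, 1,024 and 16,384 features).
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise ParameterError(f"k must be an integer, got {k!r}")
    if not 1 <= k <= MAX_K:
        raise ParameterError(f"k must be in [1, {MAX_K}], got {k}")
    vocab = tuple(iter_kmers(k))
    return KmerSpec(k=int(k), vocabulary=vocab, index={s: i for i, s in enumerate(vocab)})


def _open_maybe_gzip(path: Path) -> io.TextIOWrapper:
    """Open plain or gzip text transparently, sniffing the gzip magic bytes."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def _stream_one_file(path: Path, batch_lines: int) -> Iterator[str]:
    if batch_lines % 4 != 0 or batch_lines <= 0:
        raise ParameterError(f"batch_lines must be a positive multiple of 4, got {batch_lines}")
    n_lines = 0
    with _open_maybe_gzip(path) as handle:
        while True:
            batch = list(itertools.islice(handle, batch_lines))
            if not batch:
                break
            for offset, line in enumerate(batch):
                lineno = n_lines + offset
                phase = lineno % 4
                if phase == 0 and not line.startswith("@"):
                    raise FastqFormatError(
                        f"{path}: record {lineno // 4} header does not start with '@'"
                    )
                if phase == 1:
                    yield line.rstrip("\n").upper()
            n_lines += len(batch)
    if n_lines % 4 != 0:
        raise FastqFormatError(
            f"{path}: truncated FASTQ record {n_lines // 4} (file has {n_lines} lines, not a multiple of 4)"
        )


def stream_reads(
    paths: str | Path | Sequence[str | Path],
    batch_lines: int = DEFAULT_BATCH_LINES,
) -> Iterator[str]:
    """Stream upper-cased base sequences from one or two FASTQ(.gz) files.

    Reading proceeds in batches of ``batch_lines`` lines (default 128, i.e.
    32 records) per cycle, keeping only the sequence line of each 4-line
    record. Paired files are consumed one after the other and their reads
    pooled into a single stream; downstream counting never lets a window
    span two reads, so pooling preserves all k-mer frequencies.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not 1 <= len(paths) <= 2:
        raise ParameterError(f"expected one or two FASTQ paths, got {len(paths)}")
    for p in paths:
        p = Path(p)
        if not p.is_file():
            raise OSError(f"FASTQ file not found or unreadable: {p}")
        yield from _stream_one_file(p, batch_lines)


def count_kmers_in_sequence(
    sequence: str, spec: KmerSpec, accumulator: np.ndarray
) -> int:
    """Count every length-k window of ``sequence`` into ``accumulator``.

    Windows are 0-based half-open ``[i, i+k)`` for i in 0..len-k, forward
    strand only. Windows containing any non-ACGT symbol are skipped.
    Returns the number of skipped windows; sequences shorter than k
    contribute nothing and return 0.
    """
    k = spec.k
    if accumulator.shape != (spec.n_features,):
        raise ParameterError(
            f"accumulator length {accumulator.shape} does not match 4^{k} = {spec.n_features}"
        )
    n = len(sequence)
    if n < k:
        return 0
    codes = _BASE_CODES[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows != 255).all(axis=1)
    n_skipped = int(windows.shape[0] - valid.sum())
    if n_skipped < windows.shape[0]:
        cols = windows[valid].astype(np.int64) @ spec.powers
        accumulator += np.bincount(cols, minlength=spec.n_features)
    return n_skipped


def extract_sample_signature(
    sample_id: str,
    paths: str | Path | Sequence[str | Path],
    spec: KmerSpec,
    workers: int = 1,
    batch_lines: int = DEFAULT_BATCH_LINES,
) -> SampleSignature:
    """Stream a sample's FASTQ file(s) and return its normalized signature.

    ``workers`` is accepted for interface symmetry with cohort extraction
    (concurrency is across samples); per-sample counting is order-insensitive
    integer accumulation, so the result is identical for any worker count.
    """
    if workers < 1:
        raise ParameterError(f"workers must be >= 1, got {workers}")
    counts = np.zeros(spec.n_features, dtype=np.int64)
    n_reads = 0
    n_skipped = 0
    for seq in stream_reads(paths, batch_lines=batch_lines):
        n_skipped += count_kmers_in_sequence(seq, spec, counts)
        n_reads += 1
    total = int(counts.sum())
    if total == 0:
        raise EmptySampleError(
            f"sample {sample_id!r}: no valid {spec.k}-mer window in any read"
        )
    return SampleSignature(
        sample_id=sample_id,
        k=spec.k,
        counts_total=total,
        frequencies=counts / total,
        n_reads=n_reads,
        n_skipped_windows=n_skipped,
    )


def _extract_one(args) -> SampleSignature:
    sample_id, paths, k = args
    return extract_sample_signature(sample_id, paths, enumerate_kmers(k))


def extract_cohort(
    manifest: Sequence[tuple[str, Sequence[str | Path], str]],
    spec: KmerSpec,
    workers: int = 1,
) -> list[SampleSignature]:
    """Extract signatures for every (sample_id, paths, label) manifest row.

    Samples are processed concurrently across ``workers`` processes; each
    sample is still counted by a single worker so signatures are exactly
    reproducible.
    """
    if workers < 1:
        raise ParameterError(f"workers must be >= 1, got {workers}")
    if workers == 1:
        return [extract_sample_signature(sid, paths, spec) for sid, paths, _ in manifest]
    jobs = [(sid, [str(p) for p in paths], spec.k) for sid, paths, _ in manifest]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(_extract_one, jobs))


def read_manifest(path: str | Path) -> list[tuple[str, list[str], str]]:
    """Read a sample manifest TSV: sample_id, path1[, path2], label.

    A three-column row is single-end; a four-column row is paired-end
    (empty path2 cells are allowed and treated as single-end).
    """
    rows: list[tuple[str, list[str], str]] = []
    base = Path(path).parent
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0] != "sample_id":
            raise TableFormatError(f"{path}: manifest must start with a 'sample_id' header row")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) == 3:
                sid, p1, label = row
                paths = [p1]
            elif len(row) == 4:
                sid, p1, p2, label = row
                paths = [p1] if p2 == "" else [p1, p2]
            else:
                raise TableFormatError(f"{path}: line {lineno}: expected 3 or 4 columns, got {len(row)}")
            rows.append((sid, [str(base / p) for p in paths], label))
    return rows


def build_feature_table(
    signatures: Sequence[SampleSignature],
    labels: Mapping[str, str],
    provenance: dict | None = None,
) -> FeatureTable:
    """Consolidate per-sample signatures into one labeled samples × 4^k table.

    Rows keep input order; columns follow the lexicographic k-mer vocabulary.
    """
    if not signatures:
        raise MetadataError("no signatures to consolidate")
    ks = {s.k for s in signatures}
    if len(ks) > 1:
        raise MetadataError(f"signatures mix k values: {sorted(ks)}")
    seen: set[str] = set()
    row_labels: list[str] = []
    for s in signatures:
        if s.sample_id in seen:
            raise MetadataError(f"duplicate sample_id {s.sample_id!r}")
        seen.add(s.sample_id)
        if s.sample_id not in labels:
            raise MetadataError(f"no label for sample {s.sample_id!r}")
        row_labels.append(str(labels[s.sample_id]))
    spec = enumerate_kmers(signatures[0].k)
    matrix = np.vstack([s.frequencies for s in signatures])
    prov = {"k": spec.k, **(provenance or {})}
    return FeatureTable(
        sample_ids=[s.sample_id for s in signatures],
        feature_names=list(spec.vocabulary),
        matrix=matrix,
        labels=row_labels,
        provenance=prov,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as TSV: sample_id, <feature columns...>, label.

    Values are written with 17 significant digits so a write → read round
    trip is lossless to better than 1e-12 relative.
    """
    if table.n_samples == 0:
        raise TableFormatError("refusing to write an empty feature table (0 samples)")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", *table.feature_names, "label"])
        for sid, row, label in zip(table.sample_ids, table.matrix, table.labels):
            writer.writerow([sid, *(format(v, ".17g") for v in row), label])


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def canonicalize_table(table: FeatureTable) -> FeatureTable:
    """Fold each k-mer column into its canonical (lexicographically smaller of
    k-mer and reverse complement) column. Off by default in the pipeline —
    the feature universe is the full 4^k enumeration — but useful when strand
    of origin is uninformative."""
    k = int(table.provenance.get("k", len(table.feature_names[0])))
    spec = enumerate_kmers(k)
    if list(table.feature_names) != list(spec.vocabulary):
        raise MetadataError("canonicalization requires a full 4^k k-mer table")
    canon_cols: dict[str, int] = {}
    mapping = np.empty(spec.n_features, dtype=np.int64)
    names: list[str] = []
    for i, kmer in enumerate(spec.vocabulary):
        rc = "".join(_COMPLEMENT[b] for b in reversed(kmer))
        canon = min(kmer, rc)
        if canon not in canon_cols:
            canon_cols[canon] = len(names)
            names.append(canon)
        mapping[i] = canon_cols[canon]
    folded = np.zeros((table.n_samples, len(names)))
    np.add.at(folded.T, mapping, table.matrix.T)
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_names=names,
        matrix=folded,
        labels=list(table.labels),
        provenance={**table.provenance, "canonical": True},
    )


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table TSV written by :func:`write_feature_table`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 3 or header[0] != "sample_id" or header[-1] != "label":
            raise TableFormatError(f"{path}: line 1: header must be 'sample_id', features..., 'label'")
        feature_names = header[1:-1]
        sample_ids: list[str] = []
        labels: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise TableFormatError(
                    f"{path}: line {lineno}: expected {len(header)} columns, got {len(row)}"
                )
            sample_ids.append(row[0])
            labels.append(row[-1])
            try:
                rows.append([float(v) for v in row[1:-1]])
            except ValueError as exc:
                raise TableFormatError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise TableFormatError(f"{path}: no data rows")
    matrix = np.asarray(rows, dtype=np.float64)
    if np.isnan(matrix).any():
        bad = int(np.argwhere(np.isnan(matrix))[0, 0]) + 2
        raise TableFormatError(f"{path}: line {bad}: NA cell in feature matrix")
    provenance = {}
    lengths = {len(f) for f in feature_names}
    if len(lengths) == 1 and all(set(f) <= set(ALPHABET) for f in feature_names):
        provenance["k"] = lengths.pop()  # a k-mer table; other tables carry no k
    return FeatureTable(
        sample_ids=sample_ids,
        feature_names=feature_names,
        matrix=matrix,
        labels=labels,
        provenance=provenance,
    )
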