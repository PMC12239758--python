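"""Synthetic FASTQ cohorts and toy feature tables with controlled signal.

Reads are drawn from an order-(k_signal − 1) Markov chain over {A, C, G, T}.
Both classes share a base transition matrix; class signal is injected by
shifting the transition probabilities along a fixed zero-sum direction,
±(effect_size/2) · Δ per class, so the classes differ in k-mer composition
by a tunable amount and effect_size = 0 makes the two generative laws
identical (the null cohort). Per-sample biological variability is emulated
by resampling each sample's transition rows from a Dirichlet centered on
its class matrix with concentration ``dirichlet_alpha`` — larger α means
samples hew closer to their class composition.

Injecting signal at the composition level (rather than spiking literal
motif strings) means 3-, 5- and 7-mer tables all carry graded signal.
Quality lines are constant dummies: the k-mer extraction path ignores
quality by design.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .signature import ALPHABET, FeatureTable, enumerate_kmers

_CHARS = np.frombuffer("".join(ALPHABET).encode("ascii"), dtype=np.uint8)

DEFAULT_N_PER_CLASS = 50
DEFAULT_READS = 2000
DEFAULT_READ_LENGTH = 150
DEFAULT_K_SIGNAL = 3
DEFAULT_EFFECT = 0.2
DEFAULT_ALPHA = 1000.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative settings for a two-class synthetic cohort."""

    n_per_class: tuple[int, int] = (DEFAULT_N_PER_CLASS, DEFAULT_N_PER_CLASS)
    reads_per_sample: int = DEFAULT_READS
    read_length: int = DEFAULT_READ_LENGTH
    k_signal: int = DEFAULT_K_SIGNAL
    effect_size: float = DEFAULT_EFFECT
    dirichlet_alpha: float = DEFAULT_ALPHA
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_class, int):
            object.__setattr__(self, "n_per_class", (self.n_per_class, self.n_per_class))
        if self.effect_size < 0:
            raise ParameterError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.dirichlet_alpha <= 0:
            raise ParameterError(f"dirichlet_alpha must be > 0, got {self.dirichlet_alpha}")
        if self.k_signal < 1:
            raise ParameterError(f"k_signal must be >= 1, got {self.k_signal}")
        if self.read_length < self.k_signal:
            raise ParameterError("read_length must be at least k_signal")


def _base_and_direction(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Shared base transition matrix and the zero-sum class direction Δ.

    Rows are indexed by the 4^order context; the base alternates a mild
    AT/GC skew by context parity, and Δ pushes probability between {A, T}
    and {C, G} with opposite sign on odd contexts so the perturbation is
    spread over many k-mers.
    """
    n_ctx = 4**order
    base = np.empty((n_ctx, 4))
    delta = np.empty((n_ctx, 4))
    even_row = np.array([0.30, 0.20, 0.20, 0.30])
    odd_row = np.array([0.20, 0.30, 0.30, 0.20])
    d = np.array([0.25, -0.25, -0.25, 0.25])
    for c in range(n_ctx):
        base[c] = even_row if c % 2 == 0 else odd_row
        delta[c] = d if c % 2 == 0 else -d
    return base, delta


def class_transition_matrices(spec: SyntheticCohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Class-0 and class-1 transition matrices (4^(k_signal−1) × 4)."""
    order = spec.k_signal - 1
    base, delta = _base_and_direction(order)
    half = spec.effect_size / 2.0
    p0 = base - half * delta
    p1 = base + half * delta
    if (p0 <= 0).any() or (p1 <= 0).any():
        raise ParameterError(
            f"effect_size {spec.effect_size} drives transition probabilities non-positive; "
            "use a smaller effect_size"
        )
    return p0, p1


def perturbed_kmer_indices(spec: SyntheticCohortSpec) -> np.ndarray:
    """Columns of the k_signal-mer table whose class means are pushed apart.

    These are the k-mers whose final transition receives a positive shift
    in class 1 — useful for generator self-checks.
    """
    order = spec.k_signal - 1
    _, delta = _base_and_direction(order)
    cols = []
    for ctx in range(4**order):
        for b in range(4):
            if delta[ctx, b] > 0:
                cols.append(ctx * 4 + b)
    return np.array(cols, dtype=int)


def _sample_reads_codes(
    p_sample: np.ndarray, n_reads: int, read_length: int, order: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw reads as an (n_reads, read_length) array of base codes 0..3."""
    codes = np.empty((n_reads, read_length), dtype=np.int64)
    cum = np.cumsum(p_sample, axis=1)
    cum[:, -1] = 1.0  # guard rounding
    if order == 0:
        u = rng.random((n_reads, read_length))
        for j in range(read_length):
            codes[:, j] = (u[:, j, None] > cum[0, :3]).sum(axis=1)
        return codes
    # initial context: uniform bases
    codes[:, :order] = rng.integers(0, 4, size=(n_reads, order))
    ctx = np.zeros(n_reads, dtype=np.int64)
    for j in range(order):
        ctx = ctx * 4 + codes[:, j]
    mod = 4**order
    for j in range(order, read_length):
        u = rng.random(n_reads)
        nxt = (u[:, None] > cum[ctx, :3]).sum(axis=1)
        codes[:, j] = nxt
        ctx = (ctx * 4 + nxt) % mod
    return codes


def _sample_transitions(
    p_class: np.ndarray, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample Dirichlet jitter around the class transition matrix."""
    out = np.empty_like(p_class)
    for c in range(p_class.shape[0]):
        out[c] = rng.dirichlet(alpha * p_class[c])
    return out


def _cohort_codes(spec: SyntheticCohortSpec):
    """Yield (sample_id, class_label, codes) for every sample, deterministically."""
    p0, p1 = class_transition_matrices(spec)
    order = spec.k_signal - 1
    n0, n1 = spec.n_per_class
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(n0 + n1)
    i = 0
    for cls, n_cls, p_cls in ((0, n0, p0), (1, n1, p1)):
        for j in range(n_cls):
            rng = np.random.default_rng(children[i])
            p_sample = _sample_transitions(p_cls, spec.dirichlet_alpha, rng)
            codes = _sample_reads_codes(
                p_sample, spec.reads_per_sample, spec.read_length, order, rng
            )
            yield f"class{cls}_s{j:03d}", str(cls), codes
            i += 1


def generate_cohort_table(spec: SyntheticCohortSpec, k: int | None = None) -> FeatureTable:
    """Generate a cohort and count its k-mer table in memory (no FASTQ I/O).

    Equivalent to writing FASTQ and running extraction — reads are pure
    ACGT so no windows are skipped — but much faster for simulations.
    """
    k = k if k is not None else spec.k_signal
    kspec = enumerate_kmers(k)
    sample_ids: list[str] = []
    labels: list[str] = []
    rows: list[np.ndarray] = []
    powers = kspec.powers
    for sid, label, codes in _cohort_codes(spec):
        windows = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)
        idx = windows.reshape(-1, k) @ powers
        counts = np.bincount(idx, minlength=kspec.n_features)
        rows.append(counts / counts.sum())
        sample_ids.append(sid)
        labels.append(label)
    return FeatureTable(
        sample_ids=sample_ids,
        feature_names=list(kspec.vocabulary),
        matrix=np.vstack(rows),
        labels=labels,
        provenance={"k": k, "generator": asdict(spec)},
    )


def generate_cohort(spec: SyntheticCohortSpec, outdir: str | Path) -> Path:
    """Write a cohort as gzipped FASTQ files plus a manifest TSV.

    Returns the manifest path. The manifest schema (sample_id, path, label)
    is the same one real-data extraction consumes. A ground-truth record of
    the generative parameters is written alongside. Output is byte-stable
    under a fixed seed (gzip headers carry no timestamp).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.tsv"
    qual = "I" * spec.read_length
    rows = []
    for sid, label, codes in _cohort_codes(spec):
        fname = f"{sid}.fastq.gz"
        fpath = outdir / fname
        chars = _CHARS[codes]
        parts = []
        for r in range(codes.shape[0]):
            seq = chars[r].tobytes().decode("ascii")
            parts.append(f"@{sid}.{r}\n{seq}\n+\n{qual}\n")
        payload = "".join(parts).encode("ascii")
        with open(fpath, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", filename="", mtime=0) as gz:
                gz.write(payload)
        rows.append((sid, fname, label))
    with open(manifest_path, "w") as fh:
        fh.write("sample_id\tpath1\tlabel\n")
        for sid, fname, label in rows:
            fh.write(f"{sid}\t{fname}\t{label}\n")
    truth = asdict(spec)
    truth["perturbed_kmer_columns"] = perturbed_kmer_indices(spec).tolist()
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return manifest_path


def generate_toy_table(
    n_samples: int,
    n_features: int,
    n_informative: int,
    effect: float,
    seed: int = 0,
) -> FeatureTable:
    """Gaussian toy table: ``n_informative`` columns are mean-shifted by
    ``effect`` in class 1. Fast fixture for preprocessing/model unit tests."""
    if n_informative > n_features:
        raise ParameterError(
            f"n_informative ({n_informative}) cannot exceed n_features ({n_features})"
        )
    rng = np.random.default_rng(seed)
    n1 = n_samples // 2
    n0 = n_samples - n1
    X = rng.standard_normal((n_samples, n_features))
    y = np.array([0] * n0 + [1] * n1)
    X[y == 1, :n_informative] += effect
    width = max(3, len(str(n_features)))
    return FeatureTable(
        sample_ids=[f"toy{i:04d}" for i in range(n_samples)],
        feature_names=[f"f{j:0{width}d}" for j in range(n_features)],
        matrix=X,
        labels=[str(v) for v in y],
        provenance={
            "generator": "toy-gaussian",
            "n_informative": n_informative,
            "effect": effect,
            "seed": seed,
        },
    )
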