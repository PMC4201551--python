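"""Quality trimming and read subsampling.

Two trimming modes are provided, mirroring the two analysis suites the
pipeline emulates:

* ``error_prob_limit`` — Mott-style: convert each base's PHRED score to an
  error probability ``p_i`` and keep the contiguous subsequence maximizing
  ``sum(limit - p_i)``. Customary limits: 0.05 for the semiconductor
  platform, 0.01 for Illumina. Ambiguous bases (N) are assigned ``p = 1``
  so terminal N runs are trimmed naturally.
* ``sliding_window`` — truncate at the first window (default 20 bp) whose
  mean PHRED falls below a threshold (default 17).

Ties in the Mott maximization resolve leftmost, then longest, so trimming
is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from plastidbarcoder.seq_io import Read, ReadSet, phred_to_prob

logger = logging.getLogger(__name__)


@dataclass
class TrimParams:
    mode: str = "error_prob_limit"       # or "sliding_window"
    limit: float = 0.05
    window_length: int = 20
    window_phred: float = 17.0
    min_length: int = 30
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.limit < 1.0:
            raise ValueError("limit must lie in (0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.mode not in ("error_prob_limit", "sliding_window"):
            raise ValueError(f"unknown trim mode {self.mode!r}")

    @staticmethod
    def iontorrent() -> "TrimParams":
        return TrimParams(mode="error_prob_limit", limit=0.05, min_length=30)

    @staticmethod
    def illumina() -> "TrimParams":
        return TrimParams(mode="error_prob_limit", limit=0.01, min_length=30)

    @staticmethod
    def torrent_suite() -> "TrimParams":
        return TrimParams(mode="sliding_window", window_length=20,
                          window_phred=17.0, min_length=20)


@dataclass
class TrimReport:
    n_in: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    mean_length_in: float = 0.0
    mean_length_kept: float = 0.0


def _mott_interval(scores: list[float]) -> tuple[int, int]:
    """Return the half-open [i, j) maximizing sum(scores[i:j]).

    Ties break leftmost start, then longest. Returns (0, 0) when every
    interval has non-positive score.
    """
    n = len(scores)
    prefix = np.concatenate(([0.0], np.cumsum(scores)))
    # best = max over i<j of prefix[j]-prefix[i]
    suffix_max = np.maximum.accumulate(prefix[::-1])[::-1]  # max prefix[j], j>=i
    gains = suffix_max[1:] - prefix[:-1]  # best gain for interval starting at i
    best = float(np.max(gains)) if n else 0.0
    if best <= 0:
        return 0, 0
    i = int(np.argmax(gains >= best - 1e-12))  # leftmost start achieving best
    target = prefix[i] + best
    js = np.nonzero(np.abs(prefix - target) <= 1e-12)[0]
    j = int(js[-1])  # longest
    return i, j


def trim_read(read: Read, params: TrimParams) -> Optional[Read]:
    """Trim one read; returns None when the read is dropped."""
    n = len(read)
    if params.mode == "error_prob_limit":
        probs = [1.0 if b == "N" else phred_to_prob(q)
                 for b, q in zip(read.bases, read.quals)]
        scores = [params.limit - p for p in probs]
        i, j = _mott_interval(scores)
    else:
        w = params.window_length
        if n < w:
            mean = sum(read.quals) / n if n else 0.0
            i, j = (0, n) if mean >= params.window_phred else (0, 0)
        else:
            i, j = 0, n
            for s in range(n - w + 1):
                if sum(read.quals[s : s + w]) / w < params.window_phred:
                    j = s
                    break
    if j - i < params.min_length:
        return None
    bases = read.bases[i:j]
    if params.drop_ambiguous and "N" in bases:
        return None
    if i == 0 and j == n:
        return read
    return Read(read.id, bases, read.quals[i:j], platform=read.platform,
                mate=read.mate, pair_id=read.pair_id)


def trim_set(reads: ReadSet, params: TrimParams) -> tuple[ReadSet, TrimReport]:
    """Trim a read set, order-preserving. Orphaned mates are retained as
    singles (the surviving read keeps its pairing metadata)."""
    kept: list[Read] = []
    report = TrimReport(n_in=len(reads))
    total_in = reads.total_bases()
    for r in reads:
        t = trim_read(r, params)
        if t is None:
            report.n_dropped += 1
        else:
            kept.append(t)
    report.n_kept = len(kept)
    report.mean_length_in = total_in / len(reads) if len(reads) else 0.0
    report.mean_length_kept = (sum(len(r) for r in kept) / len(kept)
                               if kept else 0.0)
    return ReadSet(kept), report


def subsample_reads(reads: ReadSet, n: int, seed: int = 0) -> ReadSet:
    """Uniform subsample without replacement, deterministic under seed.

    Mate pairs are sampled atomically; units are accumulated in random
    order until at least ``n`` reads are collected. ``n`` beyond the
    available total returns all reads (with a logged warning).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return ReadSet([])
    if n >= len(reads):
        if n > len(reads):
            logger.warning("requested %d reads but only %d available", n, len(reads))
        return ReadSet(list(reads.reads))
    units = reads.pairs_and_singles()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    picked: list[Read] = []
    for idx in order:
        picked.extend(units[idx])
        if len(picked) >= n:
            break
    return ReadSet(picked)
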