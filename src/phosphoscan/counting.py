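"""Exact-match assignment of paired-end reads to library alleles.

A read pair is assigned to an allele only when mate 1 equals, base for base,
the first ``read_length`` bases of that allele's amplicon AND mate 2 equals
the reverse complement of its last ``read_length`` bases.  There is no
trimming, no quality filtering and no mismatch tolerance: exactness is the
only filter, and any pair failing it is tallied with a discard reason.
Because the key is the joint (prefix, suffix) pair, a single-base error can
never reassign a read to a different genotype — it can only discard it.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["Matcher", "CountResult", "AmbiguityError", "CountingError",
           "build_matcher", "count_reads", "combine_counts",
           "DISCARD_REASONS"]

DISCARD_REASONS = ("mate1_mismatch", "mate2_mismatch", "ambiguous", "invalid")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AmbiguityError(ValueError):
    """Two alleles share the same joint (prefix, suffix) sequence windows."""


class CountingError(ValueError):
    pass


@dataclass(frozen=True)
class Matcher:
    """Exact-lookup structure over allele sequence windows.

    ``joint`` maps ``(mate1 window, mate2 window)`` to a genotype;
    ``prefixes`` is the set of valid mate-1 windows, used only to attribute
    a discard to mate 1 versus mate 2.
    """

    read_length: int
    genotypes: tuple[str, ...]
    joint: Mapping[tuple[str, str], str] = field(repr=False)
    prefixes: frozenset = field(repr=False)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_matcher(alleles: Mapping[str, str], read_length: int) -> Matcher:
    """Build the exact matcher; fails fast on indistinguishable alleles.

    Raises :class:`AmbiguityError` naming the colliding genotypes when two
    alleles are identical within both sequence windows (they could never be
    told apart by exact paired-end matching).
    """
    lengths = {len(a) for a in alleles.values()}
    if len(lengths) > 1:
        raise CountingError(
            f"allele amplicons must all have equal length, got {sorted(lengths)}"
        )
    if lengths and min(lengths) < read_length:
        raise CountingError("amplicon shorter than the read window")
    joint: dict[tuple[str, str], str] = {}
    for genotype, amp in alleles.items():
        key = (amp[:read_length], _revcomp(amp[-read_length:]))
        if key in joint:
            raise AmbiguityError(
                f"alleles {joint[key]!r} and {genotype!r} are identical "
                f"within both {read_length}-bp windows"
            )
        joint[key] = genotype
    return Matcher(
        read_length=read_length,
        genotypes=tuple(alleles),
        joint=joint,
        prefixes=frozenset(k[0] for k in joint),
    )


@dataclass
class CountResult:
    """Counts for one (replicate, timepoint) sequencing sample."""

    counts: dict[str, int]
    discarded: dict[str, int]

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())

    @property
    def total(self) -> int:
        return self.n_assigned + self.n_discarded


def _open_maybe_gzip(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


_VALID = frozenset("ACGTN")


def count_reads(r1_path: str, r2_path: str, matcher: Matcher) -> CountResult:
    """Count exact-matching read pairs from a pair of FASTQ files.

    Every pair increments exactly one tally: a genotype on a joint exact
    match, else one of the discard reasons (``mate1_mismatch``,
    ``mate2_mismatch``, ``invalid`` for malformed/non-ACGTN/short records).
    Conservation — assigned + discarded = pairs read — holds by
    construction.  Mate files must be record-aligned and of equal length.
    """
    counts = {g: 0 for g in matcher.genotypes}
    discarded = {reason: 0 for reason in DISCARD_REASONS}
    joint = matcher.joint
    prefixes = matcher.prefixes
    rl = matcher.read_length
    with _open_maybe_gzip(r1_path) as f1, _open_maybe_gzip(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise CountingError(
                    "mate files have unequal record counts: "
                    f"{r1_path} vs {r2_path}"
                )
            seq1 = rec1[1].upper()
            seq2 = rec2[1].upper()
            if len(seq1) != rl or len(seq2) != rl or not (
                _VALID.issuperset(seq1) and _VALID.issuperset(seq2)
            ):
                discarded["invalid"] += 1
                continue
            genotype = joint.get((seq1, seq2))
            if genotype is not None:
                counts[genotype] += 1
            elif seq1 in prefixes:
                discarded["mate2_mismatch"] += 1
            else:
                discarded["mate1_mismatch"] += 1
    return CountResult(counts=counts, discarded=discarded)


def combine_counts(
    slices: Iterable[tuple[int, float, CountResult]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-sample results into tidy count and discard tables.

    ``slices`` yields ``(replicate, timepoint_h, result)``.  Returns
    ``(counts, discards)`` DataFrames; counts has one row per genotype per
    sample (zeros kept so every library member is present).
    """
    count_rows, discard_rows = [], []
    for rep, t, res in slices:
        for g, c in res.counts.items():
            count_rows.append((g, rep, t, c))
        for reason, c in res.discarded.items():
            discard_rows.append((rep, t, reason, c))
    counts = pd.DataFrame(
        count_rows, columns=["genotype", "replicate", "timepoint_h", "count"]
    )
    discards = pd.DataFrame(
        discard_rows, columns=["replicate", "timepoint_h", "reason", "count"]
    )
    return counts, discards
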