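"""Quality control of raw paired amplicon reads.

Stage order is fixed: 3' quality trimming, pair merging, ambiguous-base
filter, merged-length window, de novo bimera removal, primer location and
stripping.  Each stage either transforms a read or rejects it; rejections are
values, not exceptions, and per-stage tallies are conserved exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .primers import PrimerPair, reverse_complement


@dataclass
class SequenceRead:
    """A single raw read with per-base Phred qualities."""

    read_id: str
    bases: str
    quals: np.ndarray
    mate: int = 1
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > 60):
            raise ValueError("Phred scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class MergedRead:
    """An overlap-assembled read pair."""

    bases: str
    quals: np.ndarray
    sample_id: str = ""
    source_ids: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class QcConfig:
    """Thresholds of the QC stages.

    ``min_overlap=10`` encodes a strict "more than 9 bp" pair-overlap rule;
    ``max_primer_mismatches=3`` encodes "fewer than 4" mismatching bases per
    primer.  The merged-length window refers to the insert plus both primer
    flanks.
    """

    phred_floor: int = 20
    min_overlap: int = 10
    length_min: int = 272
    length_max: int = 322
    max_primer_mismatches: int = 3
    max_overlap_mismatch_fraction: float = 0.25
    chimera_parent_ratio: float = 2.0
    chimera_side_mismatches: int = 1
    chimera_end_margin: int = 30
    chimera_min_parent_divergence: int = 3
    chimera_min_side_support: int = 2
    chimera_max_parents: int = 64
    # Merged reads still carry the primer flanks when chimeras are searched;
    # breakpoints inside a flank would let any abundant template "donate" the
    # near-invariant primer head or tail and misflag rare primer variants.
    # When set, the end margin is widened to keep breakpoints in the insert.
    chimera_margin_covers_primers: bool = True

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


# --------------------------------------------------------------------------
# per-read operations
# --------------------------------------------------------------------------
def trim_tail(read: SequenceRead, phred_floor: int = 20) -> SequenceRead:
    """Trim 3' bases while the terminal base quality is below the floor."""
    good = read.quals >= phred_floor
    if not good.any():
        keep = 0
    else:
        keep = int(len(good) - np.argmax(good[::-1]))
    if keep == len(read):
        return read
    return SequenceRead(read.read_id, read.bases[:keep], read.quals[:keep], read.mate, read.sample_id)


def merge_pair(r1: SequenceRead, r2: SequenceRead, cfg: QcConfig) -> MergedRead | None:
    """Overlap-assemble a read pair, or return None when no offset qualifies.

    The mate is reverse-complemented, every overlap length from
    ``min_overlap`` up to the shorter read is scored, and the offset with the
    most matching bases wins (ties go to the longer overlap), subject to the
    mismatch-fraction ceiling.  At overlap disagreements the higher-quality
    base is kept (R1 on quality ties); agreeing positions take the larger of
    the two qualities.
    """
    len1, len2 = len(r1), len(r2)
    max_ov = min(len1, len2)
    if max_ov < cfg.min_overlap:
        return None
    a = _encode(r1.bases)
    b = _encode(reverse_complement(r2.bases))
    q2 = r2.quals[::-1]

    # matches for every relative placement of the mate via cross-correlation
    corr = np.zeros(len1 + len2 - 1)
    for base in b"ACGT":
        corr += np.correlate((a == base).astype(float), (b == base).astype(float), "full")
    ovs = np.arange(cfg.min_overlap, max_ov + 1)
    matches = corr[len1 + len2 - 1 - ovs].round().astype(int)
    mismatches = ovs - matches
    admissible = mismatches <= cfg.max_overlap_mismatch_fraction * ovs
    if not admissible.any():
        return None
    cand = np.nonzero(admissible)[0]
    best = cand[np.lexsort((ovs[cand], matches[cand]))][-1]
    ov = int(ovs[best])

    s = len1 - ov
    head_b, head_q = r1.bases[:s], r1.quals[:s]
    tail_b, tail_q = reverse_complement(r2.bases)[ov:], q2[ov:]
    o1b, o1q = a[s:], r1.quals[s:]
    o2b, o2q = b[:ov], q2[:ov]
    take2 = (o1b != o2b) & (o2q > o1q)
    cons = np.where(take2, o2b, o1b)
    consq = np.where(o1b == o2b, np.maximum(o1q, o2q), np.where(take2, o2q, o1q))
    bases = head_b + cons.tobytes().decode() + tail_b
    quals = np.concatenate([head_q, consq, tail_q])
    return MergedRead(bases, quals, r1.sample_id, (r1.read_id, r2.read_id))


def drop_ambiguous(read: MergedRead) -> bool:
    """Keep (True) iff the merged read contains no ambiguous base."""
    return "N" not in read.bases


def length_filter(read: MergedRead, cfg: QcConfig) -> bool:
    """Keep iff length_min <= len <= length_max (both bounds inclusive)."""
    return cfg.length_min <= len(read) <= cfg.length_max


def find_and_strip_primers(
    read: MergedRead, primer_pairs: Sequence[PrimerPair], cfg: QcConfig
) -> tuple[MergedRead, str] | None:
    """Locate the flanking primer pair, strip it, and report the variant.

    The forward primer must sit at the 5' terminus and the
    reverse-complemented reverse primer at the 3' terminus, each with at most
    ``max_primer_mismatches`` mismatching bases.  The best-matching variant
    wins; None means at least one terminus had no admissible match.
    """
    arr = _encode(read.bases)
    best: tuple[int, str, int, int] | None = None
    for pair in primer_pairs:
        lf, lr = len(pair.forward), len(pair.reverse)
        if len(read) < lf + lr + 1:
            continue
        mm_f = int((arr[:lf] != _encode(pair.forward)).sum())
        mm_r = int((arr[-lr:] != _encode(reverse_complement(pair.reverse))).sum())
        if mm_f <= cfg.max_primer_mismatches and mm_r <= cfg.max_primer_mismatches:
            key = (mm_f + mm_r, pair.name, lf, lr)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    _, name, lf, lr = best
    insert = MergedRead(read.bases[lf:-lr], read.quals[lf:-lr], read.sample_id, read.source_ids)
    return insert, name


# --------------------------------------------------------------------------
# chimera (bimera) removal
# --------------------------------------------------------------------------
def remove_chimeras(seq_counts: Mapping[str, int], cfg: QcConfig) -> set[str]:
    """Flag de novo bimeras among a sample's distinct merged sequences.

    A candidate is a bimera when some breakpoint at least
    ``chimera_end_margin`` bases from both ends splits it into a prefix
    matching one parent and a suffix matching another, each side with at most
    ``chimera_side_mismatches`` mismatches, where parents are previously
    accepted sequences at >= ``chimera_parent_ratio`` times the candidate's
    abundance and differ from each other by at least
    ``chimera_min_parent_divergence`` bases.  Two guards keep sequencing-error
    variants of one template from being mistaken for bimeras: the two-parent
    model must explain the candidate strictly better than either parent
    alone, and each side must carry at least ``chimera_min_side_support``
    diagnostic positions (where the candidate follows that side's parent at a
    base on which the parents disagree).  Sequences are visited in decreasing
    abundance, so parents are always non-chimeric.
    """
    if not seq_counts:
        return set()
    order = sorted(seq_counts, key=lambda s: (-seq_counts[s], s))
    max_len = max(len(s) for s in order)
    # two pads so that positions beyond a sequence's true length always mismatch
    cand_mat = np.zeros((len(order), max_len), dtype=np.uint8)
    par_mat = np.full((len(order), max_len), 255, dtype=np.uint8)
    lens = np.empty(len(order), dtype=int)
    for i, s in enumerate(order):
        enc = _encode(s)
        cand_mat[i, : len(s)] = enc
        par_mat[i, : len(s)] = enc
        lens[i] = len(s)

    margin = cfg.chimera_end_margin
    side = cfg.chimera_side_mismatches
    flagged: set[str] = set()
    accepted: list[int] = []
    counts = np.array([seq_counts[s] for s in order])
    for i, seq in enumerate(order):
        L = lens[i]
        if L < 2 * margin + 1:
            accepted.append(i)
            continue
        parents = [j for j in accepted if counts[j] >= cfg.chimera_parent_ratio * counts[i]]
        parents = parents[: cfg.chimera_max_parents]
        if len(parents) < 2:
            accepted.append(i)
            continue
        pm = par_mat[parents]
        diff = cand_mat[i][None, :L] != pm[:, :L]
        cum = np.concatenate([np.zeros((len(parents), 1), dtype=int), np.cumsum(diff, axis=1)], axis=1)
        tot = cum[:, L]
        # cheap pruning: a usable prefix parent must already fit at k = margin,
        # a usable suffix parent at k = L - margin
        pref_ok = np.nonzero(cum[:, margin] <= side)[0]
        suff_ok = np.nonzero(tot - cum[:, L - margin] <= side)[0]
        ks = np.arange(margin, L - margin + 1)
        is_chimera = False
        for ai, bi in itertools.product(pref_ok, suff_ok):
            if ai == bi:
                continue
            pa, pb = parents[ai], parents[bi]
            parent_diff = par_mat[pa][:L] != par_mat[pb][:L]
            if int(parent_diff.sum()) < cfg.chimera_min_parent_divergence:
                continue
            pref_mm = cum[ai, ks]
            suff_mm = tot[bi] - cum[bi, ks]
            model = pref_mm + suff_mm
            # diagnostic positions: candidate follows one parent where the
            # parents disagree; both sides must be supported
            left_diag = parent_diff & (cand_mat[i][:L] == par_mat[pa][:L])
            right_diag = parent_diff & (cand_mat[i][:L] == par_mat[pb][:L])
            left_cum = np.concatenate([[0], np.cumsum(left_diag)])
            right_tot = int(right_diag.sum())
            right_cum = np.concatenate([[0], np.cumsum(right_diag)])
            support = cfg.chimera_min_side_support
            ok = (
                (pref_mm <= side)
                & (suff_mm <= side)
                & (model < min(tot[ai], tot[bi]))
                & (left_cum[ks] >= support)
                & (right_tot - right_cum[ks] >= support)
            )
            if ok.any():
                is_chimera = True
                break
        if is_chimera:
            flagged.add(seq)
        else:
            accepted.append(i)
    return flagged


# --------------------------------------------------------------------------
# per-sample orchestration
# --------------------------------------------------------------------------
@dataclass
class StageCounts:
    """Read tallies in and out of every QC stage of one sample."""

    sample_id: str
    counts: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        self.counts.append((stage, n_in, n_out))

    def conserved(self) -> bool:
        return all(
            self.counts[i][2] == self.counts[i + 1][1] for i in range(len(self.counts) - 1)
        )


def run_sample_qc(
    sample_id: str,
    pairs: Iterable[tuple[SequenceRead, SequenceRead]],
    primer_pairs: Sequence[PrimerPair],
    cfg: QcConfig,
) -> tuple[list[str], StageCounts, dict[str, int]]:
    """Run the full QC chain on one sample's read pairs.

    Returns surviving insert sequences (one per read), per-stage tallies, and
    per-primer-variant counts.
    """
    pairs = list(pairs)
    tally = StageCounts(sample_id)

    merged: list[MergedRead] = []
    for r1, r2 in pairs:
        t1, t2 = trim_tail(r1, cfg.phred_floor), trim_tail(r2, cfg.phred_floor)
        m = merge_pair(t1, t2, cfg)
        if m is not None:
            merged.append(m)
    tally.add("merge", len(pairs), len(merged))

    no_n = [m for m in merged if drop_ambiguous(m)]
    tally.add("ambiguous_filter", len(merged), len(no_n))

    in_window = [m for m in no_n if length_filter(m, cfg)]
    tally.add("length_filter", len(no_n), len(in_window))

    seq_counts: dict[str, int] = {}
    for m in in_window:
        seq_counts[m.bases] = seq_counts.get(m.bases, 0) + 1
    chim_cfg = cfg
    if cfg.chimera_margin_covers_primers and primer_pairs:
        flank = max(max(len(p.forward), len(p.reverse)) for p in primer_pairs)
        margin = max(cfg.chimera_end_margin, flank + 7)
        if margin != cfg.chimera_end_margin:
            chim_cfg = replace(cfg, chimera_end_margin=margin)
    flagged = remove_chimeras(seq_counts, chim_cfg)
    no_chim = [m for m in in_window if m.bases not in flagged]
    tally.add("chimera_filter", len(in_window), len(no_chim))

    inserts: list[str] = []
    variants: dict[str, int] = {}
    for m in no_chim:
        hit = find_and_strip_primers(m, primer_pairs, cfg)
        if hit is not None:
            insert, variant = hit
            inserts.append(insert.bases)
            variants[variant] = variants.get(variant, 0) + 1
    tally.add("primer_strip", len(no_chim), len(inserts))
    return inserts, tally, variants


def sample_reads_to_pairs(sample) -> list[tuple[SequenceRead, SequenceRead]]:
    """Adapt a simulated :class:`~ednameta.simulate.SampleReads` to read pairs."""
    out = []
    for i in range(sample.n_reads):
        rid = f"{sample.sample_id}.{i + 1}"
        out.append(
            (
                SequenceRead(rid, sample.bases1[i], sample.quals1[i], 1, sample.sample_id),
                SequenceRead(rid, sample.bases2[i], sample.quals2[i], 2, sample.sample_id),
            )
        )
    return out
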