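"""Dereplication, similarity-based taxonomic assignment, OTUs, and curation.

Assignment ranks references by ungapped identity over the full query (a
seed-and-extend exact-word search, word size 11), calls a query assigned when
the top hit reaches the identity threshold (99% by default, i.e. at most one
mismatching base on a ~170 bp insert) over a minimum aligned length, and
grades each call HIGH / MODERATE / LOW by how close the runner-up species
comes.  Assigned sequences sharing a species form one OTU.  Two curation
rules then reconcile calls with a local checklist: LOW-confidence OTUs are
demoted to genus rank unless the genus has exactly one local species, and
species absent from the checklist are substituted with a designated local
relative when the checklist provides one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import ReferenceRecord

HIGH = "HIGH"
MODERATE = "MODERATE"
LOW = "LOW"
_CONFIDENCE_ORDER = {HIGH: 0, MODERATE: 1, LOW: 2}


@dataclass
class UniqueSequence:
    """A dereplicated insert with its per-sample read counts."""

    seq: str
    counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class DereplicationTally:
    n_unique: int
    n_singletons: int
    singleton_reads: int
    total_reads: int

    @property
    def clustered_reads(self) -> int:
        return self.total_reads - self.singleton_reads


def dereplicate(
    sample_inserts: Mapping[str, Sequence[str]], min_count: int = 2
) -> tuple[list[UniqueSequence], DereplicationTally]:
    """Group identical inserts across all samples; drop rare sequences.

    Sequences whose run-wide total count falls below ``min_count`` (i.e.
    singletons at the default) are discarded and tallied separately.
    """
    counts: dict[str, dict[str, int]] = {}
    total = 0
    for sample_id, inserts in sample_inserts.items():
        for seq in inserts:
            total += 1
            per = counts.setdefault(seq, {})
            per[sample_id] = per.get(sample_id, 0) + 1
    uniques = []
    n_single = reads_single = 0
    for seq in sorted(counts):
        per = counts[seq]
        n = sum(per.values())
        if n >= min_count:
            uniques.append(UniqueSequence(seq, per))
        else:
            n_single += 1
            reads_single += n
    uniques.sort(key=lambda u: (-u.total_count, u.seq))
    return uniques, DereplicationTally(len(uniques), n_single, reads_single, total)


# --------------------------------------------------------------------------
# reference search
# --------------------------------------------------------------------------
@dataclass
class Assignment:
    """Best and runner-up species hit for one unique sequence."""

    seq: str
    top_species: str | None
    top_identity: float
    second_species: str | None
    second_identity: float
    aligned_length: int
    assigned: bool
    confidence: str | None = None
    note: str = ""


@dataclass
class SearchConfig:
    min_identity: float = 99.0
    min_aligned_length: int = 100
    word_size: int = 11
    low_second_identity: float = 99.0
    moderate_margin: float = 1.0  # percentage points below the top hit


class ReferenceIndex:
    """Exact-word (k-mer) index over reference barcodes for ungapped search."""

    def __init__(self, records: Sequence[ReferenceRecord], cfg: SearchConfig | None = None):
        self.cfg = cfg or SearchConfig()
        self.records = [r for r in records if r.in_reference]
        if not self.records:
            raise ValueError("reference database is empty")
        self.by_species = {r.species: r for r in self.records}
        self._enc = [np.frombuffer(r.sequence.encode(), dtype=np.uint8) for r in self.records]
        k = self.cfg.word_size
        self._index: dict[str, list[tuple[int, int]]] = {}
        for ri, rec in enumerate(self.records):
            seq = rec.sequence
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((ri, pos))

    def _identity(self, query: np.ndarray, ri: int, diag: int) -> tuple[float, int]:
        """Percent identity of an ungapped placement; mismatch off the ends.

        ``diag`` is the reference coordinate of query position 0.  Identity is
        matches over the full query length, so query bases hanging off the
        reference count as mismatches.
        """
        ref = self._enc[ri]
        q0 = max(0, -diag)
        q1 = min(len(query), len(ref) - diag)
        if q1 <= q0:
            return 0.0, 0
        matches = int((query[q0:q1] == ref[q0 + diag : q1 + diag]).sum())
        return 100.0 * matches / len(query), q1 - q0

    def search(self, seq: str) -> Assignment:
        """Assign one sequence; see module docstring for the decision rule."""
        cfg = self.cfg
        k = cfg.word_size
        if len(seq) < k:
            return Assignment(seq, None, 0.0, None, 0.0, 0, False, note="query shorter than word size")
        query = np.frombuffer(seq.encode(), dtype=np.uint8)
        diags: set[tuple[int, int]] = set()
        for qpos in range(len(seq) - k + 1):
            for ri, rpos in self._index.get(seq[qpos : qpos + k], ()):
                diags.add((ri, rpos - qpos))
        best_by_species: dict[str, tuple[float, int]] = {}
        for ri, diag in diags:
            ident, aligned = self._identity(query, ri, diag)
            sp = self.records[ri].species
            if sp not in best_by_species or ident > best_by_species[sp][0]:
                best_by_species[sp] = (ident, aligned)
        if not best_by_species:
            return Assignment(seq, None, 0.0, None, 0.0, 0, False, note="no word match")
        ranked = sorted(best_by_species.items(), key=lambda kv: (-kv[1][0], kv[0]))
        top_sp, (top_id, top_aligned) = ranked[0]
        second_sp, second_id = (ranked[1][0], ranked[1][1][0]) if len(ranked) > 1 else (None, 0.0)
        assigned = top_id >= cfg.min_identity and top_aligned >= cfg.min_aligned_length
        return Assignment(seq, top_sp, top_id, second_sp, second_id, top_aligned, assigned)


def classify_confidence(a: Assignment, cfg: SearchConfig | None = None) -> Assignment:
    """Grade an assigned hit by the separation from the runner-up species."""
    cfg = cfg or SearchConfig()
    if not a.assigned:
        return a
    if (
        a.second_species is not None
        and a.second_species != a.top_species
        and a.second_identity >= cfg.low_second_identity
    ):
        conf = LOW
    elif (
        a.second_species is not None
        and a.second_identity >= a.top_identity - cfg.moderate_margin
    ):
        conf = MODERATE
    else:
        conf = HIGH
    return replace(a, confidence=conf)


# --------------------------------------------------------------------------
# OTUs and curation
# --------------------------------------------------------------------------
@dataclass
class OTU:
    """All unique sequences assigned to one taxon."""

    otu_id: str
    taxon: str
    rank: str  # species | genus | family
    confidence: str
    members: list[UniqueSequence]
    habitat: str = ""
    fishery: bool = False
    note: str = ""

    @property
    def counts(self) -> dict[str, int]:
        merged: dict[str, int] = {}
        for m in self.members:
            for sid, n in m.counts.items():
                merged[sid] = merged.get(sid, 0) + n
        return merged

    @property
    def total_count(self) -> int:
        return sum(m.total_count for m in self.members)


def cluster_otus(
    assigned: Sequence[tuple[UniqueSequence, Assignment]],
    reference: Mapping[str, ReferenceRecord],
) -> list[OTU]:
    """One OTU per assigned species; OTU confidence is the worst member's.

    Exact ties between species for the top hit are unresolvable at the
    marker: such sequences cluster at genus rank when the tied species share
    a genus, else at family rank, always with LOW confidence.
    """
    groups: dict[tuple[str, str], list[tuple[UniqueSequence, Assignment]]] = {}
    for u, a in assigned:
        if not a.assigned:
            continue
        taxon, rank = a.top_species, "species"
        if (
            a.second_species is not None
            and a.second_identity == a.top_identity
            and a.second_species != a.top_species
        ):
            top = reference[a.top_species]
            second = reference[a.second_species]
            if top.genus == second.genus:
                taxon, rank = f"{top.genus} sp.", "genus"
            else:
                taxon, rank = f"{top.family} sp.", "family"
            a = replace(a, confidence=LOW)
        groups.setdefault((taxon, rank), []).append((u, a))

    otus = []
    for i, ((taxon, rank), members) in enumerate(
        sorted(groups.items(), key=lambda kv: -sum(u.total_count for u, _ in kv[1]))
    ):
        worst = max((a.confidence or HIGH for _, a in members), key=_CONFIDENCE_ORDER.get)
        ref = reference.get(members[0][1].top_species)
        otus.append(
            OTU(
                otu_id=f"OTU{i + 1:04d}",
                taxon=taxon,
                rank=rank,
                confidence=worst,
                members=[u for u, _ in members],
                habitat=ref.habitat if ref else "",
                fishery=ref.fishery if ref else False,
            )
        )
    return otus


class Checklist:
    """Locally occurring species, grouped by genus, plus a substitution map.

    The substitution map sends reference species that are implausible locally
    to a designated local relative; every target must itself be local.
    """

    def __init__(
        self,
        local_species: Iterable[str],
        genus_of: Mapping[str, str],
        substitutions: Mapping[str, str] | None = None,
    ):
        self.local_species = set(local_species)
        self.genus_of = dict(genus_of)
        self.substitutions = dict(substitutions or {})
        self.local_by_genus: dict[str, set[str]] = {}
        for sp in self.local_species:
            genus = self.genus_of.get(sp, sp.split()[0])
            self.local_by_genus.setdefault(genus, set()).add(sp)
        for target in self.substitutions.values():
            if target not in self.local_species:
                raise ValueError(f"substitution target {target!r} is not in the local checklist")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Checklist":
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        local = frame.loc[frame["local"].astype(int) == 1, "species"]
        genus_of = dict(zip(frame["species"], frame["genus"]))
        subs = {
            row.species: row.substitute_for
            for row in frame.itertuples()
            if getattr(row, "substitute_for", "")
        }
        return cls(local, genus_of, subs)


def curate(otus: Sequence[OTU], checklist: Checklist) -> list[OTU]:
    """Apply the two checklist-based curation rules; deterministic, per-OTU.

    Rule 1: a LOW-confidence species-rank OTU becomes "Genus sp." unless the
    checklist lists exactly one local species in that genus, which is then
    adopted at species rank.  Rule 2: an OTU whose species is absent from the
    checklist is renamed through the substitution map when an entry exists,
    otherwise kept with a "non-local" note.  OTUs that collide on the same
    curated name are merged.
    """
    curated: list[OTU] = []
    for otu in otus:
        taxon, rank, note = otu.taxon, otu.rank, otu.note
        if otu.confidence == LOW and rank == "species":
            genus = checklist.genus_of.get(taxon, taxon.split()[0])
            local_in_genus = sorted(checklist.local_by_genus.get(genus, ()))
            if len(local_in_genus) == 1:
                taxon, note = local_in_genus[0], "rule1: single local congener"
            else:
                taxon, rank, note = f"{genus} sp.", "genus", "rule1: demoted to genus"
        elif rank == "species" and taxon not in checklist.local_species:
            if taxon in checklist.substitutions:
                note = f"rule2: substituted for {taxon}"
                taxon = checklist.substitutions[taxon]
            else:
                note = "non-local"
        curated.append(replace(otu, taxon=taxon, rank=rank, note=note))

    merged: dict[tuple[str, str], OTU] = {}
    for otu in curated:
        key = (otu.taxon, otu.rank)
        if key in merged:
            kept = merged[key]
            kept.members = kept.members + otu.members
            kept.confidence = max(
                (kept.confidence, otu.confidence), key=_CONFIDENCE_ORDER.get
            )
            if otu.note and otu.note not in kept.note:
                kept.note = "; ".join(filter(None, [kept.note, otu.note]))
        else:
            merged[key] = replace(otu, members=list(otu.members))
    return list(merged.values())


def otu_table(otus: Sequence[OTU]) -> pd.DataFrame:
    """Long-format per-sample read counts of every OTU."""
    rows = []
    for otu in otus:
        for sid, n in sorted(otu.counts.items()):
            rows.append(
                {
                    "otu_id": otu.otu_id,
                    "taxon": otu.taxon,
                    "rank": otu.rank,
                    "confidence": otu.confidence,
                    "sample_id": sid,
                    "reads": n,
                }
            )
    return pd.DataFrame(rows, columns=["otu_id", "taxon", "rank", "confidence", "sample_id", "reads"])
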