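"""Shared fixtures: small synthetic studies and brute-force oracles."""

from __future__ import annotations

import itertools

import pytest

from ednameta.pipeline import PipelineConfig, run_pipeline
from ednameta.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        n_species=15,
        n_stations=8,
        reads_per_sample=200,
        n_negative_controls=4,
    )


@pytest.fixture(scope="session")
def small_run(small_sim_config):
    """A complete small pipeline run shared across test modules."""
    cfg = PipelineConfig(sim=small_sim_config, n_perm=99)
    return run_pipeline(cfg)


# --------------------------------------------------------------------------
# brute-force oracles (kept independent of the implementation paths)
# --------------------------------------------------------------------------
COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def brute_force_merge(b1: str, b2: str, min_overlap: int, max_mm_frac: float):
    """Exhaustive overlap scan: returns (overlap, matches) of the best offset.

    The mate is reverse-complemented; every overlap length is scored by
    literal base comparison; best = most matches, ties to the longer overlap.
    """
    b2rc = revcomp(b2)
    best = None
    for ov in range(min_overlap, min(len(b1), len(b2)) + 1):
        matches = sum(
            x == y and x in "ACGT" for x, y in zip(b1[len(b1) - ov :], b2rc[:ov])
        )
        if ov - matches > max_mm_frac * ov:
            continue
        key = (matches, ov)
        if best is None or key > best:
            best = key
    if best is None:
        return None
    return best[1], best[0]


def brute_force_best_hit(query: str, references: dict[str, str]):
    """All-references, all-offsets ungapped identity scan.

    Identity is matches over the query length; query bases beyond either end
    of the reference count as mismatches.  Returns {species: best identity}.
    """
    out = {}
    for name, ref in references.items():
        best = 0.0
        for diag in range(-len(query) + 1, len(ref)):
            matches = 0
            for q in range(len(query)):
                r = q + diag
                if 0 <= r < len(ref) and query[q] == ref[r]:
                    matches += 1
            best = max(best, 100.0 * matches / len(query))
        out[name] = best
    return out


def brute_force_bimera(
    candidate: str,
    counts: dict[str, int],
    margin: int = 30,
    side_mm: int = 1,
    ratio: float = 2.0,
    min_div: int = 3,
    min_support: int = 2,
):
    """Literal restatement of the bimera rule over all breakpoints/parents."""
    cand_count = counts[candidate]
    L = len(candidate)
    parents = [s for s in counts if s != candidate and counts[s] >= ratio * cand_count]
    for a, b in itertools.permutations(parents, 2):
        pa = a[:L].ljust(L, "!")
        pb = b[:L].ljust(L, "!")
        d_ab = sum(x != y for x, y in zip(pa, pb))
        if d_ab < min_div:
            continue
        d_a = sum(x != y for x, y in zip(candidate, pa))
        d_b = sum(x != y for x, y in zip(candidate, pb))
        for k in range(margin, L - margin + 1):
            pref = sum(x != y for x, y in zip(candidate[:k], pa[:k]))
            suff = sum(x != y for x, y in zip(candidate[k:], pb[k:]))
            if pref > side_mm or suff > side_mm:
                continue
            if pref + suff >= min(d_a, d_b):
                continue
            left = sum(
                c == x != y for c, x, y in zip(candidate[:k], pa[:k], pb[:k])
            )
            right = sum(
                c == y != x for c, x, y in zip(candidate[k:], pa[k:], pb[k:])
            )
            if left >= min_support and right >= min_support:
                return True
    return False
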