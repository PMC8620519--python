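"""Shared fixtures and independent brute-force oracles.

The oracles here recompute results straight from the definitions (explicit
window enumeration, explicit path enumeration, explicit truth tables) so the
vectorised / dynamic-programming implementations are checked against an
independent route.
"""

from __future__ import annotations

import pytest

from autozygmap.io import HET, MISSING
from autozygmap.roh import ROHParams
from autozygmap.simulate import SimConfig, simulate_dataset

# Scenario used by most integration tests: study-shaped but with the WGS
# control cohort trimmed for speed where cohort size is not the point.
FAST_KW = dict(n_controls_wgs=60, n_background_variants=120, population_n=800)


@pytest.fixture(scope="session")
def sim_default():
    """Full default study-shaped dataset (12 cases, 567 controls)."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_clean():
    """Error-free (imputed-style) panel for ROH-recovery checks."""
    return simulate_dataset(SimConfig(seed=7, genotyping_error_rate=0.0, **FAST_KW))


# ---------------------------------------------------------------------------
# ROH oracle: explicit window/run enumeration
# ---------------------------------------------------------------------------

def oracle_window_fractions(codes, params: ROHParams):
    m = len(codes)
    if m == 0:
        return []
    w = min(params.window_snps, m)
    qualifies = []
    for s in range(m - w + 1):
        win = list(codes[s:s + w])
        qualifies.append(
            sum(1 for c in win if c == HET) <= params.window_het
            and sum(1 for c in win if c == MISSING) <= params.window_missing)
    fractions = []
    for i in range(m):
        starts = range(max(0, i - w + 1), min(i, m - w) + 1)
        fractions.append(sum(qualifies[s] for s in starts) / len(starts))
    return fractions


def oracle_call_roh(sample_id, codes, markers, params: ROHParams):
    """Direct run assembly from the definition; returns (start, end, n) tuples."""
    frac = oracle_window_fractions(codes, params)
    cand = [i for i in range(len(markers)) if frac[i] >= params.hit_threshold]
    runs, cur = [], []
    for i in cand:
        if cur and markers[i].pos_bp - markers[cur[-1]].pos_bp > params.max_gap_kb * 1000:
            runs.append(cur)
            cur = []
        cur.append(i)
    if cur:
        runs.append(cur)
    out = []
    for r in runs:
        start, end, n = markers[r[0]].pos_bp, markers[r[-1]].pos_bp, len(r)
        span = end - start
        if (n >= params.min_snps and span >= params.min_kb * 1000
                and span / n <= params.max_density_kb_per_snp * 1000):
            out.append((start, end, n))
    return out


# ---------------------------------------------------------------------------
# pedigree oracle: explicit path enumeration
# ---------------------------------------------------------------------------

def oracle_ancestor_paths(ped, iid):
    """ancestor -> list of path lengths, one entry per distinct path."""
    out = {}

    def dfs(node, depth):
        for p in ped.parents(node):
            out.setdefault(p, []).append(depth + 1)
            dfs(p, depth + 1)

    dfs(iid, 0)
    return out
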