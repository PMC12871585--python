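"""Poisson loading statistics and antigen-library enrichment.

Stochastic seeding of N cells over M equiprobable microwells gives a
per-site occupancy that is Binomial(N, 1/M), i.e. Poisson(lambda) with
lambda = N/M for the array sizes in play.  The expected number of
single-occupancy sites, M * lambda * exp(-lambda), is maximized at
lambda = 1 — load as many cells as there are microwells.

Enrichment analysis consumes precomputed read-count tables (one count
per library member): bulk library composition versus the members
recovered from picked microwells, as relative frequencies and fold
enrichment, plus a per-microwell dominant-member call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OccupancyModel:
    """Truncated Poisson occupancy table for one loading condition.

    The pmf is tabulated for k = 0..k_max with the tail mass beyond
    k_max folded into the last bin, so the table always sums to 1.
    """

    lam: float
    n_microwells: int
    k_max: int = None
    pmf: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.k_max is None:
            self.k_max = max(20, math.ceil(self.lam + 10 * math.sqrt(max(self.lam, 1e-12))))
        p = stats.poisson.pmf(np.arange(self.k_max + 1), self.lam)
        p[-1] += stats.poisson.sf(self.k_max, self.lam)  # fold the tail
        self.pmf = p
        assert abs(self.pmf.sum() - 1.0) < 1e-9

    def expected_counts(self) -> np.ndarray:
        return self.n_microwells * self.pmf


def occupancy_pmf(lam: float, k: int) -> float:
    """P(occupancy = k) under Poisson loading: lam^k e^-lam / k!."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if k < 0 or not float(k).is_integer():
        raise ValueError("k must be a non-negative integer")
    return float(stats.poisson.pmf(int(k), lam))


def expected_singles(n_cells: int, n_microwells: int) -> float:
    """Expected number of single-occupancy microwells.

    M * lambda * exp(-lambda) with lambda = n_cells/n_microwells;
    unimodal in n_cells with its maximum where loaded cells equal the
    number of microwells (lambda = 1).
    """
    if n_microwells < 1:
        raise ValueError("need at least one microwell")
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    lam = n_cells / n_microwells
    return float(n_microwells * lam * math.exp(-lam))


def loading_chisquare(occupancy: np.ndarray, lam: float, min_expected: float = 5.0):
    """Chi-square goodness of fit of an occupancy sample to Poisson(lam).

    Bins with expected count below ``min_expected`` are pooled from the
    right.  Returns (statistic, p_value, dof).
    """
    occupancy = np.asarray(occupancy, dtype=int)
    n = len(occupancy)
    model = OccupancyModel(lam=lam, n_microwells=n)
    observed = np.bincount(occupancy, minlength=model.k_max + 1)[: model.k_max + 1]
    # occupancies beyond the table fold into the last bin, like the model tail
    overflow = (occupancy > model.k_max).sum()
    observed[-1] += overflow
    expected = model.expected_counts()

    # pool right-to-left until every bin clears the expected-count floor
    obs_b, exp_b = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed[::-1], expected[::-1]):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_b.append(acc_o)
            exp_b.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and obs_b:
        obs_b[-1] += acc_o
        exp_b[-1] += acc_e
    obs_b, exp_b = np.asarray(obs_b[::-1]), np.asarray(exp_b[::-1])
    stat, p = stats.chisquare(obs_b, exp_b * obs_b.sum() / exp_b.sum())
    return float(stat), float(p), len(obs_b) - 1


# ---------------------------------------------------------------------------
# enrichment


def enrichment_table(bulk_counts: pd.Series | dict, recovered_counts: pd.Series | dict) -> pd.DataFrame:
    """Relative abundance of library members: bulk pool vs recovered picks.

    Frequencies are normalized within each column; fold enrichment is
    recovered_freq / bulk_freq.  Members absent from the recovered set
    get fold 0; members absent from the bulk (library dropouts) get the
    +inf sentinel rather than an exception.
    """
    bulk = pd.Series(bulk_counts, dtype=float)
    rec = pd.Series(recovered_counts, dtype=float)
    if bulk.empty or rec.empty:
        raise ValueError("empty count table")
    if (bulk < 0).any() or (rec < 0).any():
        raise ValueError("counts must be non-negative")
    members = bulk.index.union(rec.index)
    bulk = bulk.reindex(members, fill_value=0.0)
    rec = rec.reindex(members, fill_value=0.0)
    if bulk.sum() == 0 or rec.sum() == 0:
        raise ValueError("count column sums to zero")
    bulk_freq = bulk / bulk.sum()
    rec_freq = rec / rec.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(
            bulk_freq > 0, rec_freq / bulk_freq, np.where(rec_freq > 0, np.inf, 0.0)
        )
    out = pd.DataFrame(
        {
            "member": members,
            "bulk_count": bulk.to_numpy(),
            "bulk_freq": bulk_freq.to_numpy(),
            "recovered_count": rec.to_numpy(),
            "recovered_freq": rec_freq.to_numpy(),
            "fold_enrichment": fold,
        }
    ).set_index("member")
    return out


def dominant_antigen(
    per_microwell_reads: pd.DataFrame, min_fraction: float = 0.5
) -> pd.Series:
    """Per-microwell dominant library member, or 'ambiguous'.

    Rows are microwells, columns library members.  The call is the
    member with the largest read fraction when that fraction reaches
    ``min_fraction``; ties and all-zero rows are 'ambiguous'.
    """
    reads = per_microwell_reads.astype(float)
    if (reads.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    calls = []
    for _, row in reads.iterrows():
        total = row.sum()
        if total == 0:
            calls.append("ambiguous")
            continue
        frac = row / total
        top = frac.max()
        winners = frac.index[frac == top]
        if len(winners) > 1 or top < min_fraction:
            calls.append("ambiguous")
        else:
            calls.append(str(winners[0]))
    return pd.Series(calls, index=reads.index, name="dominant_antigen")


def screening_yield(
    n_wells: int,
    microwells_per_well: float,
    p_single_A: float,
    p_single_B_given_A: float,
) -> float:
    """Expected number of 1:1 co-culture microwells from sequential loading.

    n_wells * microwells_per_well * P(single A) * P(single B | single A).
    """
    for p in (p_single_A, p_single_B_given_A):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    return float(n_wells * microwells_per_well * p_single_A * p_single_B_given_A)
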