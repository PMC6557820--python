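"""Knowledge-based contact potentials for normal and entangled contacts.

Following the classic quasi-chemical recipe, the propensity of amino acids
a and b to be in contact is converted to an energy-like score by comparing
the contact frequency f_c(a,b) = N_c(a,b)/N_c with the generic pair
frequency f(a,b) = N(a,b)/N:

    E_norm(a,b) = −τ log( f_c(a,b) / f(a,b) ),       τ = 100.

Restricting the contacts to the closures of entangled loops gives the
entangled-contact potential E_GE, and the difference is the enrichment
score

    ΔE_enr(a,b) = −τ log( f_c^G(a,b) / f_c(a,b) ) = E_GE − E_norm,

negative where a pair is over-represented at the ends of entangled loops.
All pair universes are restricted to sequence separation ≥ m0 = 10 so the
minimum-length constraint on loops cannot bias the comparison. Counts are
of unordered pairs, each counted once; uncertainties come from
bootstrapping whole proteins (101 resamplings), preserving within-protein
correlations. Entries whose counts are zero are left undefined (masked),
with no pseudocounts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .structure_io import AA_INDEX, AMINO_ACIDS, ChainTrace
from .gaussian import (
    CONTACT_CUTOFF, M0, LoopRecord, compute_contacts, enumerate_loops,
    scan_loops,
)

TAU = 100.0
N_BOOTSTRAP = 101

_TRIU = np.triu_indices(20)  # 210 unordered pairs incl. diagonal


def _pair_index_matrix() -> np.ndarray:
    """Map (a, b) label indices to a canonical unordered-pair slot 0..209."""
    slot = np.zeros((20, 20), dtype=int)
    for k, (a, b) in enumerate(zip(*_TRIU)):
        slot[a, b] = slot[b, a] = k
    return slot


_PAIR_SLOT = _pair_index_matrix()


def _count_label_pairs(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Accumulate unordered label pairs into a length-210 count vector."""
    valid = (codes_a >= 0) & (codes_b >= 0)
    if not valid.any():
        return np.zeros(210)
    return np.bincount(
        _PAIR_SLOT[codes_a[valid], codes_b[valid]], minlength=210
    ).astype(float)


def _codes(trace: ChainTrace) -> np.ndarray:
    return np.array([AA_INDEX.get(r, -1) for r in trace.residues])


@dataclass
class PairCounts:
    """Generic-pair, contact and entangled-contact counts of an ensemble.

    Per-protein count vectors (length 210, canonical unordered-pair order)
    are retained so the bootstrap can resample whole proteins.
    """

    per_protein_pairs: np.ndarray  # (P, 210)
    per_protein_contacts: np.ndarray
    per_protein_entangled: np.ndarray

    @property
    def n_proteins(self) -> int:
        return len(self.per_protein_pairs)

    @property
    def pairs(self) -> np.ndarray:
        return self.per_protein_pairs.sum(axis=0)

    @property
    def contacts(self) -> np.ndarray:
        return self.per_protein_contacts.sum(axis=0)

    @property
    def entangled(self) -> np.ndarray:
        return self.per_protein_entangled.sum(axis=0)

    @property
    def N(self) -> float:
        return float(self.pairs.sum())

    @property
    def Nc(self) -> float:
        return float(self.contacts.sum())

    @property
    def NcG(self) -> float:
        return float(self.entangled.sum())


def count_pairs(trace: ChainTrace, m0: int = M0) -> np.ndarray:
    """Generic (combinatorial) pairs at separation ≥ m0 for one chain."""
    codes = _codes(trace)
    i, j = np.triu_indices(trace.n, k=m0)
    return _count_label_pairs(codes[i], codes[j])


def count_contacts(
    trace: ChainTrace,
    m0: int = M0,
    cutoff: float = CONTACT_CUTOFF,
    mode: str = "sidechain_heavy",
) -> np.ndarray:
    """Contact pairs at separation ≥ m0 for one chain (side-chain heavy
    atoms by default; glycine falls back to all heavy atoms)."""
    codes = _codes(trace)
    cmap = compute_contacts(trace, cutoff=cutoff, mode=mode)
    pairs = enumerate_loops(cmap, m0=m0)
    if not pairs:
        return np.zeros(210)
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    return _count_label_pairs(codes[i], codes[j])


def count_entangled_contacts(
    trace: ChainTrace,
    loops: list[LoopRecord],
    m0: int = M0,
    cutoff: float = CONTACT_CUTOFF,
    mode: str = "sidechain_heavy",
) -> np.ndarray:
    """Closing contacts of entangled loops (|G'_c(i)| ≥ 1) for one chain.

    The closing pair must also satisfy the potential-mode contact criterion
    (side-chain heavy atoms within the cutoff); closures that only meet the
    any-heavy-atom criterion are skipped.
    """
    codes = _codes(trace)
    cmap = compute_contacts(trace, cutoff=cutoff, mode=mode)
    valid = set(cmap.contacts)
    ent = [(r.i1, r.i2) for r in loops
           if r.entangled and r.i2 - r.i1 >= m0 and (r.i1, r.i2) in valid]
    if not ent:
        return np.zeros(210)
    i = np.array([p[0] for p in ent])
    j = np.array([p[1] for p in ent])
    return _count_label_pairs(codes[i], codes[j])


def count_ensemble(
    traces: list[ChainTrace],
    loop_records: list[list[LoopRecord]] | None = None,
    m0: int = M0,
    cutoff: float = CONTACT_CUTOFF,
    mode: str = "sidechain_heavy",
    loop_cutoff: float | None = None,
) -> PairCounts:
    """Accumulate all three count families over an ensemble.

    ``loop_records`` may carry precomputed per-structure entanglement scans;
    otherwise each structure is scanned here (loop closures use the
    any-heavy-atom criterion at ``loop_cutoff``, defaulting to ``cutoff``).
    """
    pp, pc, pe = [], [], []
    for k, trace in enumerate(traces):
        if loop_records is not None:
            loops = loop_records[k]
        else:
            loops = scan_loops(trace, cutoff=loop_cutoff or cutoff, m0=m0)
        pp.append(count_pairs(trace, m0=m0))
        pc.append(count_contacts(trace, m0=m0, cutoff=cutoff, mode=mode))
        pe.append(count_entangled_contacts(trace, loops, m0=m0, cutoff=cutoff,
                                           mode=mode))
    return PairCounts(
        per_protein_pairs=np.array(pp),
        per_protein_contacts=np.array(pc),
        per_protein_entangled=np.array(pe),
    )


@dataclass
class PotentialMatrix:
    """Symmetric 20×20 score matrix with bootstrap errors and a mask.

    ``values`` are on the τ scale; undefined entries (zero counts) are NaN.
    ``mask`` flags entries whose |value| exceeds the bootstrap stderr.
    """

    values: np.ndarray
    stderr: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def significant(self) -> np.ndarray:
        if self.stderr is None:
            return self.defined
        return self.defined & (np.abs(self.values) > self.stderr)

    def triu_values(self) -> np.ndarray:
        """The 210 unordered-pair entries (NaN where undefined)."""
        return self.values[_TRIU]


def _score_vector(num: np.ndarray, den: np.ndarray, tau: float) -> np.ndarray:
    """−τ log of the ratio of two (frequency-normalized) count vectors."""
    n_tot, d_tot = num.sum(), den.sum()
    if n_tot <= 0 or d_tot <= 0:
        raise ValueError("empty count vector: potential undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -tau * np.log((num / n_tot) / (den / d_tot))
    out[(num <= 0) | (den <= 0)] = np.nan
    return out


def _to_matrix(vec: np.ndarray) -> np.ndarray:
    m = np.full((20, 20), np.nan)
    m[_TRIU] = vec
    m[(_TRIU[1], _TRIU[0])] = vec
    return m


def potential(counts: PairCounts, which: str = "norm", tau: float = TAU) -> PotentialMatrix:
    """E_norm (contacts vs generic pairs) or E_GE (entangled contacts vs
    generic pairs) on the τ scale."""
    if which == "norm":
        num = counts.contacts
    elif which == "ge":
        num = counts.entangled
    else:
        raise ValueError("which must be 'norm' or 'ge'")
    return PotentialMatrix(values=_to_matrix(_score_vector(num, counts.pairs, tau)))


def enrichment(counts: PairCounts, tau: float = TAU) -> PotentialMatrix:
    """ΔE_enr = −τ log(f_c^G / f_c) = E_GE − E_norm (entrywise)."""
    return PotentialMatrix(
        values=_to_matrix(_score_vector(counts.entangled, counts.contacts, tau))
    )


def bootstrap_errors(
    counts: PairCounts,
    n_resamples: int = N_BOOTSTRAP,
    seed: int = 0,
    tau: float = TAU,
) -> dict[str, np.ndarray]:
    """Bootstrap standard errors for E_norm, E_GE and ΔE_enr.

    Proteins (not individual contacts) are resampled with replacement;
    the stderr of each matrix entry is the standard deviation of its score
    across resamples, ignoring resamples where the entry is undefined.
    """
    rng = np.random.default_rng(seed)
    p = counts.n_proteins
    scores = {"norm": [], "ge": [], "enr": []}
    for _ in range(n_resamples):
        idx = rng.integers(0, p, size=p)
        pairs = counts.per_protein_pairs[idx].sum(axis=0)
        cont = counts.per_protein_contacts[idx].sum(axis=0)
        ent = counts.per_protein_entangled[idx].sum(axis=0)
        scores["norm"].append(_score_vector(cont, pairs, tau))
        if ent.sum() > 0:
            scores["ge"].append(_score_vector(ent, pairs, tau))
            scores["enr"].append(_score_vector(ent, cont, tau))
        else:  # resample (or ensemble) without entangled contacts
            scores["ge"].append(np.full(210, np.nan))
            scores["enr"].append(np.full(210, np.nan))
    out = {}
    for key, vals in scores.items():
        arr = np.array(vals)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # entries undefined in every resample yield all-NaN slices
            warnings.simplefilter("ignore", RuntimeWarning)
            out[key] = _to_matrix(np.nanstd(arr, axis=0, ddof=1))
    return out


@dataclass
class CorrelationReport:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    slope: float
    n_pairs: int


def correlation_analysis(
    enr: PotentialMatrix, norm: PotentialMatrix
) -> CorrelationReport:
    """Pearson/Spearman correlation and linear-fit slope of ΔE_enr vs
    E_norm over the jointly defined unordered pairs."""
    x = norm.triu_values()
    y = enr.triu_values()
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError(f"only {ok.sum()} jointly defined pairs")
    x, y = x[ok], y[ok]
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return CorrelationReport(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        slope=slope, n_pairs=int(ok.sum()),
    )


def rank_by_average_potential(norm: PotentialMatrix) -> list[str]:
    """Amino acids ordered by increasing row/column-average E_norm (the
    display ordering of the potential heat maps)."""
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(norm.values, axis=0)
    order = np.argsort(avg)
    return [AMINO_ACIDS[k] for k in order]
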