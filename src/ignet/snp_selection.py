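"""Fisher exact-test screening of SNPs against the binary diagnosis.

Each SNP's 2x3 contingency table (diagnosis x dosage) is tested with the
Freeman–Halton extension of Fisher's exact test: the two-sided p-value is the
sum of the conditional probabilities — multivariate hypergeometric with all
margins fixed — of every 2x3 table whose probability does not exceed that of
the observed table. SNPs with p below the selection threshold (default 0.01,
strict inequality, no multiple-testing correction) are retained in genomic
order, and the APOE e4 allele count is appended afterwards as a specially
flagged token that is exempt from the threshold.

An allelic 2x2 mode (alternate vs. reference allele counts, plain Fisher)
is available behind the ``mode`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact as _fisher_2x2

APOE_TOKEN = "APOE_e4"

#: relative tolerance applied toward inclusion when comparing table
#: probabilities against the observed table's probability
PROB_TOL = 1e-12

#: refuse to enumerate tables above this total by default
DEFAULT_ENUMERATION_CAP = 10_000


def genotype_contingency(dosages, labels) -> np.ndarray:
    """2 (label) x 3 (dosage 0/1/2) count table."""
    dosages = np.asarray(dosages)
    labels = np.asarray(labels)
    if dosages.size == 0:
        raise ValueError("empty input")
    if dosages.shape != labels.shape:
        raise ValueError("dosages and labels have different lengths")
    if not np.isin(dosages, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0, 1, 2} (impute missing first)")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    table = np.zeros((2, 3), dtype=np.int64)
    np.add.at(table, (labels.astype(int), dosages.astype(int)), 1)
    return table


@lru_cache(maxsize=100_000)
def _margin_grid(r0: int, r1: int, c0: int, c1: int, c2: int):
    """All attainable 2x3 tables with the given margins, as flat arrays.

    Tables are parameterized by the two free cells (a, b) of the first row;
    returns (a_values, b_values, log_probabilities) over the feasible grid.
    """
    a = np.arange(min(r0, c0) + 1)
    b = np.arange(min(r0, c1) + 1)
    A, B = np.meshgrid(a, b, indexing="ij")
    X2 = r0 - A - B
    feasible = (X2 >= 0) & (X2 <= c2)
    A, B, X2 = A[feasible], B[feasible], X2[feasible]
    cells = np.stack([A, B, X2, c0 - A, c1 - B, c2 - X2])
    n = r0 + r1
    const = (gammaln(r0 + 1) + gammaln(r1 + 1) + gammaln(c0 + 1)
             + gammaln(c1 + 1) + gammaln(c2 + 1) - gammaln(n + 1))
    logp = const - gammaln(cells + 1.0).sum(axis=0)
    return A, B, logp


def fisher_exact_2x3(table, enumeration_cap: int = DEFAULT_ENUMERATION_CAP) -> float:
    """Two-sided Freeman–Halton exact p-value of a 2x3 table.

    Monomorphic tables (a single occupied row or column) return 1.0.
    """
    table = np.asarray(table)
    if table.shape != (2, 3):
        raise ValueError("expected a 2x3 table")
    if (table < 0).any():
        raise ValueError("negative count")
    n = int(table.sum())
    if n == 0:
        raise ValueError("empty table")
    if n > enumeration_cap:
        raise ValueError(f"table total {n} exceeds enumeration cap {enumeration_cap}")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows > 0).sum() <= 1 or (cols > 0).sum() <= 1:
        return 1.0
    A, B, logp = _margin_grid(int(rows[0]), int(rows[1]),
                              int(cols[0]), int(cols[1]), int(cols[2]))
    obs = (A == table[0, 0]) & (B == table[0, 1])
    logp_obs = logp[obs][0]
    p = np.exp(logp[logp <= logp_obs + np.log1p(PROB_TOL)]).sum()
    return float(min(p, 1.0))


def fisher_pvalues_for_margins(r0: int, r1: int, c0: int, c1: int, c2: int):
    """Exact p-values of *every* 2x3 table with the given margins at once.

    Returns (a, b, p) flat arrays where (a, b) are the two free first-row
    cells. Shares the enumeration with ``fisher_exact_2x3`` but resolves all
    tables of the margin class in one sorted cumulative sum; used for
    exhaustive sweeps where calling the scalar API per table would repeat the
    enumeration needlessly.
    """
    if min(r0, r1) == 0 or (np.array([c0, c1, c2]) > 0).sum() <= 1:
        A, B, _ = _margin_grid(r0, r1, c0, c1, c2)
        return A, B, np.ones(A.size)
    A, B, logp = _margin_grid(r0, r1, c0, c1, c2)
    order = np.argsort(logp)
    cum = np.cumsum(np.exp(logp[order]))
    # rank of the largest log-prob still within tolerance of each table's own
    idx = np.searchsorted(logp[order], logp + np.log1p(PROB_TOL), side="right")
    p = np.minimum(cum[idx - 1], 1.0)
    return A, B, p


def _allelic_p(dosages, labels) -> float:
    """2x2 allelic Fisher test: alternate vs. reference allele counts."""
    alt = np.array([dosages[labels == c].sum() for c in (0, 1)])
    tot = np.array([2 * (labels == c).sum() for c in (0, 1)])
    table = np.column_stack([tot - alt, alt])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(_fisher_2x2(table, alternative="two-sided")[1])


@dataclass
class SelectedPanel:
    """Ordered SNP panel surviving the threshold, plus the flagged APOE token."""

    snp_ids: list
    p_values: np.ndarray          # np.nan at the APOE position
    alpha: float = 0.01
    apoe_position: int | None = None

    def __post_init__(self):
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.snp_ids) != len(self.p_values):
            raise ValueError("snp_ids and p_values lengths differ")
        if self.apoe_position is not None:
            if self.snp_ids[self.apoe_position] != APOE_TOKEN:
                raise ValueError("apoe_position does not point at the APOE token")
        tested = np.delete(self.p_values, self.apoe_position) \
            if self.apoe_position is not None else self.p_values
        if tested.size and not (tested < self.alpha).all():
            raise ValueError("a retained p-value is not below alpha")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def has_apoe(self) -> bool:
        return self.apoe_position is not None

    def to_frame(self) -> pd.DataFrame:
        is_apoe = np.zeros(len(self), dtype=int)
        if self.has_apoe:
            is_apoe[self.apoe_position] = 1
        return pd.DataFrame({"snp_id": self.snp_ids,
                             "p_value": self.p_values,
                             "is_apoe": is_apoe})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, alpha: float = 0.01) -> "SelectedPanel":
        df = pd.read_csv(path, sep="\t")
        apoe = np.flatnonzero(df["is_apoe"].to_numpy() == 1)
        return cls(snp_ids=df["snp_id"].tolist(),
                   p_values=df["p_value"].to_numpy(),
                   alpha=alpha,
                   apoe_position=int(apoe[0]) if apoe.size else None)


def select_snps(genotypes, labels: pd.Series, alpha: float = 0.01,
                training_ids=None, mode: str = "genotypic"):
    """Screen every SNP; retain those with p < alpha in genomic order.

    Parameters
    ----------
    genotypes
        ``GenotypeMatrix`` (or its subjects x SNPs dosage DataFrame).
    labels
        Binary series indexed by subject id (1 = AD).
    training_ids
        Subjects on which the tests are computed; default all shared subjects.
        Restricting to the training partition avoids selection leakage into
        validation and test subjects.
    mode
        ``"genotypic"`` (2x3 Freeman–Halton, the dosage coding) or
        ``"allelic"`` (2x2 allele-count Fisher).

    Returns
    -------
    (SelectedPanel, pandas.DataFrame)
        The panel (without APOE; see ``append_apoe``) and the full per-SNP
        test report (snp_id, p_value, selected).
    """
    dosages = getattr(genotypes, "dosages", genotypes)
    if dosages.shape[1] == 0:
        raise ValueError("no SNPs to test")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if mode not in ("genotypic", "allelic"):
        raise ValueError("mode must be 'genotypic' or 'allelic'")
    ids = dosages.index.intersection(labels.index)
    if training_ids is not None:
        ids = ids.intersection(pd.Index(training_ids))
    if len(ids) == 0:
        raise ValueError("no subjects shared between genotypes and labels")
    sub = dosages.loc[ids]
    y = labels.loc[ids].to_numpy().astype(int)
    pvals = np.empty(sub.shape[1])
    for j, snp in enumerate(sub.columns):
        d = sub[snp].to_numpy()
        if np.isnan(d).any():
            raise ValueError(f"missing dosages at {snp}; impute before selection")
        if mode == "genotypic":
            pvals[j] = fisher_exact_2x3(genotype_contingency(d.astype(int), y))
        else:
            pvals[j] = _allelic_p(d.astype(int), y)
    selected = pvals < alpha
    report = pd.DataFrame({"snp_id": sub.columns, "p_value": pvals,
                           "selected": selected})
    panel = SelectedPanel(snp_ids=list(sub.columns[selected]),
                          p_values=pvals[selected], alpha=alpha)
    return panel, report


def append_apoe(panel: SelectedPanel) -> SelectedPanel:
    """Append the APOE e4 allele-count token at the final position.

    The token is exempt from the p-value threshold and flagged so the genetic
    channel assigns it a distinct embedding vocabulary.
    """
    if panel.has_apoe or APOE_TOKEN in panel.snp_ids:
        raise ValueError("APOE token already present in the panel")
    return SelectedPanel(snp_ids=list(panel.snp_ids) + [APOE_TOKEN],
                         p_values=np.append(panel.p_values, np.nan),
                         alpha=panel.alpha,
                         apoe_position=len(panel.snp_ids))
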