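"""ΔΔCt fold induction and Group A–D classification of TNFα-activated genes.

Fold induction is computed per genotype against its own unstimulated (t = 0)
calibrator with a reference gene (ΔΔCt).  A gene is TNFα-activated if its mean
wild-type fold induction at 1 h is at least 2-fold.  For each activated gene
and each interaction-defective RelA mutant — RelA(TA2), which cannot engage
CBP/p300 TAZ1, and RelA(Ser276Ala), which cannot engage KIX — an expression
defect is called when the wild-type-minus-mutant difference in log2 fold
induction is positive and its confidence interval excludes zero.  Genes are
then grouped: A defective in both mutants, B in the TAZ1-binding mutant only,
C in the Ser276 mutant only, D in neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("wt", "TA2", "S276A")
DEFAULT_THRESHOLD = 2.0     # fold
DEFAULT_TIME = 60.0         # minutes (1 h)
DEFAULT_CONFIDENCE = 0.95

REQUIRED_COLUMNS = ("gene", "genotype", "time_min", "replicate", "fold_induction")


def ddct_fold(ct_gene_t: float, ct_ref_t: float,
              ct_gene_0: float, ct_ref_0: float) -> float:
    """Fold induction by the ΔΔCt method: 2^−ΔΔCt.

    ΔΔCt = (Ct_gene − Ct_ref) at time t minus the same difference at the
    calibrator (t = 0); the reference gene normalizes loading.
    """
    for v in (ct_gene_t, ct_ref_t, ct_gene_0, ct_ref_0):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_gene_t - ct_ref_t) - (ct_gene_0 - ct_ref_0)
    return float(2.0 ** (-ddct))


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    return table


def call_activated(table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                   time: float = DEFAULT_TIME) -> list[str]:
    """Genes whose mean wild-type fold induction at ``time`` is ≥ ``threshold``.

    The boundary is inclusive ("at least 2-fold").  Genes with no wild-type
    data at the time point are excluded with a warning.
    """
    import warnings
    _check_table(table)
    wt = table[(table["genotype"] == "wt") & (table["time_min"] == time)]
    activated = []
    for gene in pd.unique(table["gene"]):
        sub = wt[wt["gene"] == gene]
        if sub.empty:
            warnings.warn(f"gene {gene!r}: no wild-type data at t={time}; excluded")
            continue
        if sub["fold_induction"].mean() >= threshold:
            activated.append(gene)
    return activated


@dataclass(frozen=True)
class DefectCall:
    """Outcome of one wt-vs-mutant expression-defect comparison."""
    defective: bool
    difference: float            # mean log2(wt) − mean log2(mutant)
    ci_low: float                # lower bound of the central CI on the difference
    ci_high: float
    confidence: float
    n_wt: int
    n_mut: int


def call_defect(table: pd.DataFrame, gene: str, mutant: str,
                confidence: float = DEFAULT_CONFIDENCE,
                time: float = DEFAULT_TIME) -> DefectCall:
    """Expression-defect call for ``gene`` in ``mutant`` relative to wild type.

    Welch (unequal-variance) comparison of log2 fold inductions at the given
    time.  Defective iff the difference (wt − mutant) is positive and its
    central ``confidence`` interval excludes zero.  The calls are nested in the
    confidence level: any gene defective at 95% is defective at 67%.
    """
    _check_table(table)
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    sel = table[(table["gene"] == gene) & (table["time_min"] == time)]
    wt = sel[sel["genotype"] == "wt"]["fold_induction"].to_numpy(dtype=float)
    mu = sel[sel["genotype"] == mutant]["fold_induction"].to_numpy(dtype=float)
    if wt.size < 2 or mu.size < 2:
        raise ValueError(f"gene {gene!r}: need >= 2 replicates per genotype "
                         f"(wt {wt.size}, {mutant} {mu.size})")
    lw, lm = np.log2(np.maximum(wt, 1e-12)), np.log2(np.maximum(mu, 1e-12))
    diff = float(lw.mean() - lm.mean())
    se = float(np.sqrt(lw.var(ddof=1) / lw.size + lm.var(ddof=1) / lm.size))
    if se == 0.0:
        ci_low = ci_high = diff
        return DefectCall(defective=diff > 0, difference=diff, ci_low=ci_low,
                          ci_high=ci_high, confidence=confidence,
                          n_wt=wt.size, n_mut=mu.size)
    # Welch–Satterthwaite degrees of freedom
    vw, vm = lw.var(ddof=1) / lw.size, lm.var(ddof=1) / lm.size
    df = (vw + vm) ** 2 / (vw ** 2 / (lw.size - 1) + vm ** 2 / (lm.size - 1))
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    ci_low, ci_high = diff - tcrit * se, diff + tcrit * se
    return DefectCall(defective=(diff > 0 and ci_low > 0), difference=diff,
                      ci_low=ci_low, ci_high=ci_high, confidence=confidence,
                      n_wt=wt.size, n_mut=mu.size)


GROUP_RULES = {(True, True): "A", (True, False): "B",
               (False, True): "C", (False, False): "D"}


@dataclass(frozen=True)
class GroupAssignment:
    gene: str
    group: str                       # A | B | C | D
    defect_ta2: bool
    defect_s276a: bool
    sort_key: float                  # wt − TA2 log2 difference at 1 h
    group_at_67: str | None = None   # relabel under the relaxed confidence

    def __post_init__(self) -> None:
        if GROUP_RULES[(self.defect_ta2, self.defect_s276a)] != self.group:
            raise ValueError("group inconsistent with defect calls")


def assign_groups(table: pd.DataFrame, activated: Iterable[str] | None = None,
                  confidence: float = DEFAULT_CONFIDENCE,
                  relaxed_confidence: float | None = 0.67,
                  threshold: float = DEFAULT_THRESHOLD,
                  time: float = DEFAULT_TIME) -> pd.DataFrame:
    """Group every TNFα-activated gene by its mutant defect pattern.

    Groups: A — defective in both RelA(TA2) and RelA(Ser276Ala); B — TA2 only;
    C — S276A only; D — neither.  Output sorted by the wild-type-minus-TA2
    log2 difference at the activation time (largest defect first).  When
    ``relaxed_confidence`` is given, a second pass at that level records the
    group each gene would switch to (``group_at_67``; equal to the primary
    group when no switch occurs).  Genes with missing defect calls are
    reported with group ``unclassified``.
    """
    _check_table(table)
    if activated is None:
        activated = call_activated(table, threshold=threshold, time=time)
    rows = []
    for gene in activated:
        try:
            c_ta2 = call_defect(table, gene, "TA2", confidence, time)
            c_s276 = call_defect(table, gene, "S276A", confidence, time)
        except ValueError:
            rows.append({"gene": gene, "group": "unclassified",
                         "defect_ta2": None, "defect_s276a": None,
                         "sort_key": np.nan, "group_at_67": None})
            continue
        group = GROUP_RULES[(c_ta2.defective, c_s276.defective)]
        g67 = None
        if relaxed_confidence is not None:
            r_ta2 = call_defect(table, gene, "TA2", relaxed_confidence, time)
            r_s276 = call_defect(table, gene, "S276A", relaxed_confidence, time)
            g67 = GROUP_RULES[(r_ta2.defective, r_s276.defective)]
        rows.append({"gene": gene, "group": group,
                     "defect_ta2": c_ta2.defective,
                     "defect_s276a": c_s276.defective,
                     "sort_key": c_ta2.difference, "group_at_67": g67})
    df = pd.DataFrame(rows, columns=["gene", "group", "defect_ta2",
                                     "defect_s276a", "sort_key", "group_at_67"])
    return df.sort_values("sort_key", ascending=False, na_position="last") \
             .reset_index(drop=True)


def group_sizes(assignments: pd.DataFrame) -> dict[str, int]:
    counts = assignments["group"].value_counts()
    return {g: int(counts.get(g, 0)) for g in ("A", "B", "C", "D", "unclassified")
            if g != "unclassified" or counts.get(g, 0)}
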