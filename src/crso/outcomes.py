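"""Rule-versus-event survival comparison with permutation-adjusted p-values.

For a consensus rule R containing event E, patients satisfying R (all of R's
events) are compared against patients harboring E but not satisfying R, by a
univariate Cox proportional-hazards fit on the group indicator over
progression-free intervals.  A positive Z score means the rule group fares
better.  Because the comparisons for one event are dependent, multiplicity is
handled per event by permutation: the (time, status) pairs of E's carriers
are scrambled and the smallest p over that event's rule comparisons is
recorded per iteration; the adjusted p-value of a rule is the fraction of
iterations whose minimum p is strictly smaller than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import BinaryEventMatrix
from .rules import Rule, rule_label


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (e.g. PFI days) and event indicator."""

    samples: list[str]
    time: np.ndarray
    observed: np.ndarray  # 1 = progression/death observed, 0 = censored

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.observed = np.asarray(self.observed, dtype=int)
        if (self.time < 0).any():
            raise ValueError("negative survival time")
        if len(self.samples) != len(self.time) or len(self.time) != len(self.observed):
            raise ValueError("survival table columns differ in length")


def read_survival(path) -> SurvivalTable:
    """TSV with columns: sample, PFI_time, PFI_event."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    s = df[cols.get("sample", df.columns[0])].astype(str).tolist()
    t = df[cols.get("pfi_time", df.columns[1])].to_numpy(dtype=float)
    e = df[cols.get("pfi_event", df.columns[2])].to_numpy(dtype=int)
    return SurvivalTable(s, t, e)


@dataclass
class AssociationResult:
    event: str
    rule: Rule
    n_rule: int
    n_event_only: int
    z: float | None
    p: float | None
    p_adj: float | None = None
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.z is not None


def _cox_groups(
    time: np.ndarray, observed: np.ndarray, group: np.ndarray
) -> tuple[float, float] | None:
    """Univariate Cox PH Wald test of a binary group indicator.

    Newton iteration on the Breslow partial likelihood, specialized to a
    single binary covariate (the score and information reduce to sums over
    unique event times of at-risk group counts), so the permutation loop
    stays fast.  Returns (z, p), with the sign flipped so positive z means
    group 1 (the rule group) has *better* outcomes (lower hazard); None on
    degenerate data (no observed events, one-group input, or monotone
    likelihood).
    """
    if observed.sum() == 0 or len(np.unique(group)) < 2:
        return None
    order = np.argsort(time, kind="stable")
    t = np.asarray(time, dtype=float)[order]
    e = np.asarray(observed, dtype=bool)[order]
    x = np.asarray(group, dtype=float)[order]
    ev_times = np.unique(t[e])
    if len(ev_times) == 0:
        return None
    # at-risk counts per unique event time (t sorted ascending)
    first_at_risk = np.searchsorted(t, ev_times, side="left")
    total_after = len(t) - first_at_risk
    csum_x = np.concatenate([[0.0], np.cumsum(x)])
    n1 = csum_x[-1] - csum_x[first_at_risk]
    n0 = total_after - n1
    # events per unique time, overall and in group 1
    d = np.zeros(len(ev_times))
    d1 = np.zeros(len(ev_times))
    pos = np.searchsorted(ev_times, t[e])
    np.add.at(d, pos, 1.0)
    np.add.at(d1, pos, x[e])
    D1 = d1.sum()
    beta = 0.0
    info = 0.0
    for _ in range(40):
        eb = np.exp(beta)
        s_ratio = n1 * eb / (n0 + n1 * eb)
        score = D1 - float((d * s_ratio).sum())
        info = float((d * s_ratio * (1.0 - s_ratio)).sum())
        if info <= 1e-12:
            return None
        step = score / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(beta) > 15:  # monotone likelihood / complete separation
            return None
        if abs(score) < 1e-9:
            break
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return -float(z), p  # negative coef (lower hazard in group 1) -> positive z


def rule_vs_event(
    surv: SurvivalTable,
    d: BinaryEventMatrix,
    rule: Rule,
    event: str,
    min_group: int = 10,
) -> AssociationResult:
    """Compare samples satisfying ``rule`` with samples harboring ``event``
    but not satisfying the rule.  Both groups must have >= ``min_group``
    patients, else the pair is skipped."""
    if event not in rule:
        raise ValueError(f"event {event!r} is not part of rule {rule_label(rule)}")
    idx = {lab: i for i, lab in enumerate(d.event_labels)}
    sat = d.values[[idx[e] for e in rule]].all(axis=0)
    has_event = d.values[idx[event]]
    s_index = {s: k for k, s in enumerate(d.samples)}
    pos = np.array([s_index[s] for s in surv.samples if s in s_index])
    keep_mask = np.array([s in s_index for s in surv.samples])
    time = surv.time[keep_mask]
    observed = surv.observed[keep_mask]
    rule_grp = sat[pos]
    event_grp = has_event[pos] & ~rule_grp
    n_r, n_e = int(rule_grp.sum()), int(event_grp.sum())
    if n_r < min_group or n_e < min_group:
        return AssociationResult(event, rule, n_r, n_e, None, None, note="group too small")
    sel = rule_grp | event_grp
    fit = _cox_groups(time[sel], observed[sel], rule_grp[sel])
    if fit is None:
        return AssociationResult(event, rule, n_r, n_e, None, None, note="untestable")
    z, p = fit
    return AssociationResult(event, rule, n_r, n_e, z, p)


def permutation_adjust(
    surv: SurvivalTable,
    d: BinaryEventMatrix,
    event: str,
    rules_containing_event: list[Rule],
    rng: np.random.Generator,
    n_perm: int = 1000,
    min_group: int = 10,
) -> list[AssociationResult]:
    """Permutation-adjusted p-values for all rule-vs-event tests of one event.

    Each permutation scrambles the (time, status) pairs among the samples
    carrying the event, preserving carrier-set sizes and the marginal
    survival distribution; P_adj is the fraction of permutations whose
    minimum p over the event's testable rules is strictly below the rule's
    observed p.
    """
    observed_results = [
        rule_vs_event(surv, d, r, event, min_group) for r in rules_containing_event
    ]
    testable = [r for r in observed_results if r.testable]
    if not testable:
        return observed_results
    idx = {lab: i for i, lab in enumerate(d.event_labels)}
    s_index = {s: k for k, s in enumerate(d.samples)}
    keep_mask = np.array([s in s_index for s in surv.samples])
    pos = np.array([s_index[s] for s in surv.samples if s in s_index])
    time = surv.time[keep_mask].copy()
    observed = surv.observed[keep_mask].copy()
    carriers = np.flatnonzero(d.values[idx[event]][pos])
    group_masks = []
    for res in testable:
        sat = d.values[[idx[e] for e in res.rule]].all(axis=0)[pos]
        has_event = d.values[idx[event]][pos]
        group_masks.append((sat, has_event & ~sat))
    min_ps = np.empty(n_perm)
    for it in range(n_perm):
        perm = rng.permutation(len(carriers))
        t_perm = time.copy()
        o_perm = observed.copy()
        t_perm[carriers] = time[carriers][perm]
        o_perm[carriers] = observed[carriers][perm]
        best = np.inf
        for sat, ev_only in group_masks:
            sel = sat | ev_only
            fit = _cox_groups(t_perm[sel], o_perm[sel], sat[sel])
            if fit is not None:
                best = min(best, fit[1])
        min_ps[it] = best
    for res in testable:
        res.p_adj = float((min_ps < res.p).mean())
    return observed_results


def multi_rule_events(con_gcrs: list[Rule]) -> list[str]:
    """Events appearing in more than one consensus rule (the auto-selected
    test set for outcome association)."""
    counts: dict[str, int] = {}
    for r in con_gcrs:
        for e in r:
            counts[e] = counts.get(e, 0) + 1
    return sorted(e for e, c in counts.items() if c >= 2)


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "event": r.event,
                "rule": rule_label(r.rule),
                "NR": r.n_rule,
                "NE": r.n_event_only,
                "Z": r.z,
                "P": r.p,
                "P_adj": r.p_adj,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)
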