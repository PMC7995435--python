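"""Build the categorical, binary and penalty matrices from raw annotations.

Mutations (MAF-like table restricted to significantly mutated genes) are
classified per gene and sample into hotspot (HS), in-frame indel (I), splice
(S) or loss (L) observations; copy-number events come from GISTIC2-style
focal values thresholded into weak/strong amplifications and deletions at
the peak level.  Passenger probabilities are patient-, gene- and
observation-type-specific:

* HS / L: sums of per-amino-acid substitution rates at / away from hotspot
  positions (rates are inputs, e.g. from a selection-intensity model);
* I / S: cohort control-gene frequencies scaled by protein length / 480;
* copy number: control-cytoband rates times per-sample burden factors
  (with +0.5 smoothing);
* every probability is multiplied by the sample's adjustment factor and
  capped at 0.95 before taking the negative log.

Genes significant both as mutated and copy-number altered merge into hybrid
mutDel / mutAmp events whose co-observation penalty is the sum of the parts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    CategoricalEventMatrix,
    EventDef,
    PenaltyMatrix,
    binarize,
    format_code,
)

PROB_CAP = 0.95
PROB_FLOOR = 1e-12  # keeps penalties finite if an input rate degenerates to 0
MEAN_PROTEIN_LENGTH = 480.0
COPY_NEUTRAL = 0.3
HOTSPOT_MIN_SAMPLES = 3

VARIANT_CLASSES = (
    "missense",
    "silent",
    "nonsense",
    "splice",
    "frameshift-indel",
    "in-frame-indel",
    "intronic",
    "other",
)

#: MAF Variant_Classification values -> internal classes
MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "silent": "silent",
    "synonymous": "silent",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "splice_site": "splice",
    "splice_region": "splice",
    "frame_shift_del": "frameshift-indel",
    "frame_shift_ins": "frameshift-indel",
    "frameshift-indel": "frameshift-indel",
    "in_frame_del": "in-frame-indel",
    "in_frame_ins": "in-frame-indel",
    "in-frame-indel": "in-frame-indel",
    "intron": "intronic",
    "intronic": "intronic",
    "nonstop_mutation": "other",
    "translation_start_site": "other",
    "other": "other",
}

# classes counting as single amino-acid substitutions (hotspot-eligible,
# except silent/intronic which never change the protein)
SUBSTITUTION_CLASSES = {"missense", "nonsense", "splice"}
# classes contributing a non-silent alteration (anything but silent/intronic)
NONSILENT_CLASSES = {
    "missense",
    "nonsense",
    "splice",
    "frameshift-indel",
    "in-frame-indel",
    "other",
}


class PenaltyBuildError(ValueError):
    pass


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene: str
    variant_class: str
    amino_acid_position: int | None = None

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            raise PenaltyBuildError(
                f"unknown variant class {self.variant_class!r} "
                f"({self.gene}/{self.sample_id})"
            )


_AA_POS_RE = re.compile(r"^p\.[A-Za-z*]+(\d+)")


def parse_protein_position(protein_change: str | None) -> int | None:
    """Extract the amino-acid position from an HGVS-style protein change
    (e.g. ``p.V600E`` -> 600).  Returns None when unannotated."""
    if not protein_change or not isinstance(protein_change, str):
        return None
    m = _AA_POS_RE.match(protein_change.strip())
    return int(m.group(1)) if m else None


def read_maf(path, strict: bool = False) -> list[MutationRecord]:
    """Read a MAF-like TSV (columns: sample, gene, variant_classification,
    protein_change; common MAF column aliases accepted)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise PenaltyBuildError(f"missing column (one of {names}) in {path}")

    s_col = pick("sample", "tumor_sample_barcode", "sample_id")
    g_col = pick("gene", "hugo_symbol")
    v_col = pick("variant_classification", "variant_class")
    p_col = None
    for n in ("protein_change", "hgvsp_short", "amino_acid_change"):
        if n in cols:
            p_col = cols[n]
            break
    records = []
    for row in df.itertuples(index=False):
        raw = str(getattr(row, v_col)).strip().lower()
        vclass = MAF_CLASS_MAP.get(raw)
        if vclass is None:
            if strict:
                raise PenaltyBuildError(f"unknown variant classification {raw!r}")
            continue
        pos = parse_protein_position(getattr(row, p_col)) if p_col else None
        records.append(
            MutationRecord(str(getattr(row, s_col)), str(getattr(row, g_col)), vclass, pos)
        )
    return records


# ---------------------------------------------------------------------------
# Mutation classification
# ---------------------------------------------------------------------------

def hotspot_positions(
    records: list[MutationRecord], min_samples: int = HOTSPOT_MIN_SAMPLES
) -> dict[str, set[int]]:
    """Amino-acid positions altered by substitutions in >= ``min_samples``
    distinct samples (silent/intronic never count; samples count once per
    position regardless of how many substitutions they carry there)."""
    carriers: dict[tuple[str, int], set[str]] = {}
    for r in records:
        if r.variant_class in SUBSTITUTION_CLASSES and r.amino_acid_position is not None:
            carriers.setdefault((r.gene, r.amino_acid_position), set()).add(r.sample_id)
    out: dict[str, set[int]] = {}
    for (gene, pos), samples in carriers.items():
        if len(samples) >= min_samples:
            out.setdefault(gene, set()).add(pos)
    return out


def classify_mutations(
    records: list[MutationRecord],
    smgs: list[str],
    cohort: list[str],
    min_hotspot_samples: int = HOTSPOT_MIN_SAMPLES,
) -> tuple[CategoricalEventMatrix, dict[str, set[int]]]:
    """One observation code per (SMG, sample); precedence HS > I > S > L.

    Hotspot detection uses the whole cohort.  A splice substitution at a
    recurrent position is a hotspot; non-recurrent single-substitution splice
    events are S; any other non-silent, non-intronic mutation is L.
    """
    smg_set = set(smgs)
    hs_pos = hotspot_positions([r for r in records if r.gene in smg_set], min_hotspot_samples)
    cell: dict[tuple[str, str], str] = {}
    rank = {"HS": 0, "I": 1, "S": 2, "L": 3}

    def better(old: str | None, new: str) -> str:
        return new if old is None or rank[new] < rank[old] else old

    for r in records:
        if r.gene not in smg_set:
            continue
        key = (r.gene, r.sample_id)
        code = None
        if (
            r.variant_class in SUBSTITUTION_CLASSES
            and r.amino_acid_position is not None
            and r.amino_acid_position in hs_pos.get(r.gene, ())
        ):
            code = "HS"
        elif r.variant_class == "in-frame-indel":
            code = "I"
        elif r.variant_class == "splice" and r.amino_acid_position is not None:
            code = "S"
        elif r.variant_class in NONSILENT_CLASSES:
            code = "L"
        if code is not None:
            cell[key] = better(cell.get(key), code)

    events = [EventDef(g, f"{g}-M", "mutation") for g in smgs]
    codes = [
        [frozenset([cell[(g, s)]]) if (g, s) in cell else frozenset() for s in cohort]
        for g in smgs
    ]
    return CategoricalEventMatrix(events, list(cohort), codes), hs_pos


# ---------------------------------------------------------------------------
# Patient adjustment factors
# ---------------------------------------------------------------------------

@dataclass
class PatientAdjustment:
    counts: pd.Series      # capped mutation counts per sample
    factors: pd.Series     # count / cohort mean


def patient_adjustments(
    records: list[MutationRecord], smgs: list[str], cohort: list[str]
) -> PatientAdjustment:
    """Per-sample burden factor from point mutations outside the SMGs.

    Samples with zero such mutations get count 1; counts above ten times the
    75th percentile are capped there; factors are counts over the cohort mean
    of the capped counts.
    """
    if not cohort:
        raise PenaltyBuildError("empty cohort")
    smg_set = set(smgs)
    counts = pd.Series(0, index=list(cohort), dtype=float)
    point_classes = SUBSTITUTION_CLASSES | {"silent"}
    for r in records:
        if r.gene not in smg_set and r.variant_class in point_classes:
            if r.sample_id in counts.index:
                counts[r.sample_id] += 1
    counts = counts.clip(lower=1)
    cap = 10 * counts.quantile(0.75)
    counts = counts.clip(upper=cap)
    factors = counts / counts.mean()
    return PatientAdjustment(counts, factors)


# ---------------------------------------------------------------------------
# Mutation passenger probabilities
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionRateTable:
    """Per-SMG per-amino-acid-substitution rates plus protein lengths."""

    rates: pd.DataFrame           # columns: gene, position, rate
    protein_lengths: dict[str, int]

    def __post_init__(self):
        need = {"gene", "position", "rate"}
        if not need.issubset(self.rates.columns):
            raise PenaltyBuildError(f"rate table needs columns {sorted(need)}")
        if (self.rates["rate"] < 0).any():
            raise PenaltyBuildError("negative substitution rate")

    def gene_rate_split(self, gene: str, hotspots: set[int]) -> tuple[float, float]:
        """(sum of rates at hotspot positions, sum elsewhere) for a gene."""
        sub = self.rates[self.rates["gene"] == gene]
        at = sub["position"].isin(list(hotspots))
        return float(sub.loc[at, "rate"].sum()), float(sub.loc[~at, "rate"].sum())


@dataclass
class ControlGeneStats:
    """Cohort frequencies of in-frame indels and splice mutations per control
    gene per sample (population-level; scaled by protein length / 480)."""

    inframe_rate: float
    splice_rate: float


def control_gene_stats(
    records: list[MutationRecord], control_genes: list[str], n_samples: int
) -> ControlGeneStats:
    ctl = set(control_genes)
    if not ctl or n_samples == 0:
        raise PenaltyBuildError("control-gene stats need control genes and samples")
    n_if = sum(1 for r in records if r.gene in ctl and r.variant_class == "in-frame-indel")
    n_sp = sum(1 for r in records if r.gene in ctl and r.variant_class == "splice")
    denom = len(ctl) * n_samples
    return ControlGeneStats(n_if / denom, n_sp / denom)


def mutation_passenger_probs(
    m_mut: CategoricalEventMatrix,
    rates: SubstitutionRateTable,
    control_stats: ControlGeneStats,
    adjustments: PatientAdjustment,
    hotspots: dict[str, set[int]],
) -> np.ndarray:
    """Passenger probability per cell of the mutation matrix (1 on wild type)."""
    ne, ns = m_mut.shape
    probs = np.ones((ne, ns))
    for i, ev in enumerate(m_mut.events):
        gene = ev.event_id
        gene_hs = hotspots.get(gene, set())
        hs_rate, loss_rate = rates.gene_rate_split(gene, gene_hs)
        length = rates.protein_lengths.get(gene)
        for j, sample in enumerate(m_mut.samples):
            cell = m_mut.codes[i][j]
            if not cell:
                continue
            (code,) = cell
            if code == "HS":
                base = hs_rate
            elif code == "L":
                base = loss_rate
            else:
                if length is None:
                    raise PenaltyBuildError(f"missing protein length for {gene}")
                scale = length / MEAN_PROTEIN_LENGTH
                base = (
                    control_stats.inframe_rate if code == "I" else control_stats.splice_rate
                ) * scale
            prob = base * float(adjustments.factors[sample])
            probs[i, j] = min(max(prob, PROB_FLOOR), PROB_CAP)
    return probs


# ---------------------------------------------------------------------------
# Copy-number thresholding
# ---------------------------------------------------------------------------

def gene_cnv_code(value: float, low_cut: float, high_cut: float) -> str:
    """Code a focal copy-number value: neutral in [-0.3, 0.3], strong beyond
    the sample-specific cutoffs."""
    if value > COPY_NEUTRAL:
        return "SA" if value > high_cut else "WA"
    if value < -COPY_NEUTRAL:
        return "SD" if value < low_cut else "WD"
    return "Z"


def threshold_cnv(
    focal_by_gene: pd.DataFrame,
    sample_cutoffs: pd.DataFrame,
    amp_peaks: dict[str, list[str]],
    del_peaks: dict[str, list[str]],
) -> tuple[CategoricalEventMatrix, CategoricalEventMatrix]:
    """Peak-level amplification and deletion matrices by the extreme method.

    ``focal_by_gene`` is genes × samples; ``sample_cutoffs`` has columns
    ``low``/``high`` indexed by sample.  Each amplification event takes the
    code of the *maximum* focal value over its peak genes (deletions inside
    an amplification peak are wild type), and vice versa for deletions.
    """
    samples = [str(c) for c in focal_by_gene.columns]
    for name, genes in {**amp_peaks, **del_peaks}.items():
        missing = [g for g in genes if g not in focal_by_gene.index]
        if missing:
            raise PenaltyBuildError(f"peak {name}: genes {missing} absent from focal matrix")
    low = sample_cutoffs["low"].reindex(samples)
    high = sample_cutoffs["high"].reindex(samples)
    if low.isna().any() or high.isna().any():
        raise PenaltyBuildError("sample cutoffs missing for some samples")

    def build(peaks: dict[str, list[str]], amp: bool) -> CategoricalEventMatrix:
        suffix = "-A" if amp else "-D"
        etype = "amplification" if amp else "deletion"
        events, codes = [], []
        for name, genes in peaks.items():
            vals = focal_by_gene.loc[genes, samples].to_numpy(dtype=float)
            extreme = vals.max(axis=0) if amp else vals.min(axis=0)
            row = []
            for j, s in enumerate(samples):
                code = gene_cnv_code(float(extreme[j]), float(low[s]), float(high[s]))
                if amp and code in ("WD", "SD"):
                    code = "Z"
                if not amp and code in ("WA", "SA"):
                    code = "Z"
                row.append(frozenset() if code == "Z" else frozenset([code]))
            events.append(EventDef(name, f"{name}{suffix}", etype))
            codes.append(row)
        return CategoricalEventMatrix(events, samples, codes)

    return build(amp_peaks, amp=True), build(del_peaks, amp=False)


# ---------------------------------------------------------------------------
# Copy-number passenger probabilities
# ---------------------------------------------------------------------------

@dataclass
class CytobandRates:
    mu_sd: float
    mu_wd: float
    mu_sa: float
    mu_wa: float
    f_amp: pd.Series  # per-sample amplification burden factor
    f_del: pd.Series

    def cell_prob(self, code: str, sample: str) -> float:
        if code == "SD":
            return self.mu_sd * float(self.f_del[sample])
        if code == "WD":
            return self.mu_wd * float(self.f_del[sample])
        if code == "SA":
            return self.mu_sa * float(self.f_amp[sample])
        if code == "WA":
            return self.mu_wa * float(self.f_amp[sample])
        raise PenaltyBuildError(f"no copy-number rate for code {code!r}")


def cnv_passenger_probs(control_cytobands: pd.DataFrame) -> CytobandRates:
    """Rates from a control-cytoband code matrix (cytobands × samples).

    Weak rates pool weak and strong counts, so the weak-event probability is
    the frequency of observing *any* alteration in that direction; +0.5
    smoothing keeps per-sample factors positive.
    """
    if control_cytobands.size == 0:
        raise PenaltyBuildError("no control cytobands")
    arr = control_cytobands.to_numpy(dtype=str)
    nm = arr.size
    c_sd = int((arr == "SD").sum())
    c_wd = int((arr == "WD").sum())
    c_sa = int((arr == "SA").sum())
    c_wa = int((arr == "WA").sum())
    mu_sd = c_sd / nm
    mu_sa = c_sa / nm
    mu_wd = (c_sd + c_wd) / nm
    mu_wa = (c_sa + c_wa) / nm
    amp_counts = pd.Series(
        ((arr == "SA") | (arr == "WA")).sum(axis=0), index=control_cytobands.columns, dtype=float
    )
    del_counts = pd.Series(
        ((arr == "SD") | (arr == "WD")).sum(axis=0), index=control_cytobands.columns, dtype=float
    )
    f_amp = (amp_counts + 0.5) / (amp_counts.mean() + 0.5)
    f_del = (del_counts + 0.5) / (del_counts.mean() + 0.5)
    return CytobandRates(mu_sd, mu_wd, mu_sa, mu_wa, f_amp, f_del)


def cnv_cell_probs(m_cnv: CategoricalEventMatrix, rates: CytobandRates) -> np.ndarray:
    ne, ns = m_cnv.shape
    probs = np.ones((ne, ns))
    for i in range(ne):
        for j, sample in enumerate(m_cnv.samples):
            cell = m_cnv.codes[i][j]
            if not cell:
                continue
            (code,) = cell
            prob = rates.cell_prob(code, sample)
            probs[i, j] = min(max(prob, PROB_FLOOR), PROB_CAP)
    return probs


# ---------------------------------------------------------------------------
# Hybrid merging -> final (M, D, P)
# ---------------------------------------------------------------------------

def merge_hybrids(
    mut_m: CategoricalEventMatrix,
    amp_m: CategoricalEventMatrix,
    del_m: CategoricalEventMatrix,
    mut_probs: np.ndarray,
    amp_probs: np.ndarray,
    del_probs: np.ndarray,
    peak_genes_amp: dict[str, list[str]] | None = None,
    peak_genes_del: dict[str, list[str]] | None = None,
    exceptions: dict[str, str] | None = None,
):
    """Merge mutation and copy-number events; create hybrid events for genes
    significant in both.  Returns (M, D, P).

    A hybrid cell's code is the union of the mutation and copy-number codes
    and its penalty the sum of the two penalties (independent co-observation).
    ``exceptions`` maps gene -> 'mutamp'/'mutdel' for genes hybridizing with
    both peak directions.
    """
    samples = mut_m.samples
    if amp_m.samples != samples or del_m.samples != samples:
        raise PenaltyBuildError("matrices must share the sample ordering")
    exceptions = exceptions or {}
    peak_genes_amp = peak_genes_amp if peak_genes_amp is not None else {
        e.event_id: [e.event_id] for e in amp_m.events
    }
    peak_genes_del = peak_genes_del if peak_genes_del is not None else {
        e.event_id: [e.event_id] for e in del_m.events
    }
    smg_list = [e.event_id for e in mut_m.events]
    amp_hit = {
        g: e.event_id
        for e in amp_m.events
        for g in peak_genes_amp.get(e.event_id, [])
        if g in smg_list
    }
    del_hit = {
        g: e.event_id
        for e in del_m.events
        for g in peak_genes_del.get(e.event_id, [])
        if g in smg_list
    }
    hybrid_kind: dict[str, str] = {}
    for g in smg_list:
        in_a, in_d = g in amp_hit, g in del_hit
        if in_a and in_d:
            kind = exceptions.get(g)
            if kind not in ("mutamp", "mutdel"):
                raise PenaltyBuildError(
                    f"gene {g} lies in both an amplification and a deletion peak; "
                    "add an exception entry choosing mutamp or mutdel"
                )
            hybrid_kind[g] = kind
        elif in_a:
            hybrid_kind[g] = exceptions.get(g, "mutamp")
        elif in_d:
            hybrid_kind[g] = exceptions.get(g, "mutdel")

    consumed_amp = {amp_hit[g] for g, k in hybrid_kind.items() if k == "mutamp"}
    consumed_del = {del_hit[g] for g, k in hybrid_kind.items() if k == "mutdel"}

    events: list[EventDef] = []
    codes: list[list[frozenset]] = []
    probs_rows: list[np.ndarray] = []

    mut_idx = {e.event_id: i for i, e in enumerate(mut_m.events)}
    amp_idx = {e.event_id: i for i, e in enumerate(amp_m.events)}
    del_idx = {e.event_id: i for i, e in enumerate(del_m.events)}

    for g in smg_list:
        i = mut_idx[g]
        if g not in hybrid_kind:
            events.append(mut_m.events[i])
            codes.append(list(mut_m.codes[i]))
            probs_rows.append(mut_probs[i].copy())
            continue
        kind = hybrid_kind[g]
        if kind == "mutamp":
            k = amp_idx[amp_hit[g]]
            cnv_codes, cnv_p = amp_m.codes[k], amp_probs[k]
            label, etype = f"{g}-MA", "mutamp"
        else:
            k = del_idx[del_hit[g]]
            cnv_codes, cnv_p = del_m.codes[k], del_probs[k]
            label, etype = f"{g}-MD", "mutdel"
        row_codes, row_probs = [], np.ones(len(samples))
        for j in range(len(samples)):
            union = mut_m.codes[i][j] | cnv_codes[j]
            row_codes.append(union)
            if union:
                prob = 1.0
                if mut_m.codes[i][j]:
                    prob *= mut_probs[i][j]
                if cnv_codes[j]:
                    prob *= cnv_p[j]
                row_probs[j] = prob
        events.append(EventDef(g, label, etype))
        codes.append(row_codes)
        probs_rows.append(row_probs)

    for e in amp_m.events:
        if e.event_id in consumed_amp:
            continue
        k = amp_idx[e.event_id]
        events.append(e)
        codes.append(list(amp_m.codes[k]))
        probs_rows.append(amp_probs[k].copy())
    for e in del_m.events:
        if e.event_id in consumed_del:
            continue
        k = del_idx[e.event_id]
        events.append(e)
        codes.append(list(del_m.codes[k]))
        probs_rows.append(del_probs[k].copy())

    m = CategoricalEventMatrix(events, list(samples), codes)
    d = binarize(m)
    prob_grid = np.vstack(probs_rows)
    penalties = np.where(d.values, -np.log(np.clip(prob_grid, PROB_FLOOR, None)), 0.0)
    p = PenaltyMatrix(d.event_labels, list(samples), penalties)
    return m, d, p


# ---------------------------------------------------------------------------
# Simplified penalty variants
# ---------------------------------------------------------------------------

def _cell_type_key(cell: frozenset) -> tuple[str, ...]:
    return tuple(sorted(cell))


def simplified_penalties(
    m: CategoricalEventMatrix,
    p: PenaltyMatrix,
    mode: str,
    global_means: dict[str, float] | None = None,
) -> PenaltyMatrix:
    """Fixed-penalty variants of ``P``.

    ``FC``: each observation type gets the cohort mean penalty of its
    instances (multi-code cells sum their component types).  ``FG``: supplied
    per-type global values.  ``U``: a single fixed penalty, -log(0.1), for
    every altered cell (any fixed probability gives the same downstream
    ranking).  Wild-type cells stay 0.
    """
    if mode not in ("FC", "FG", "U"):
        raise ValueError(f"unknown simplification mode {mode!r}")
    ne, ns = m.shape
    out = np.zeros((ne, ns))
    if mode == "U":
        fixed = -math.log(0.1)
        for i in range(ne):
            for j in range(ns):
                if m.codes[i][j]:
                    out[i, j] = fixed
        return PenaltyMatrix(list(p.event_labels), list(p.samples), out)

    if mode == "FC":
        # each observation type (hybrid co-observations counted as their own
        # composite type) takes the cohort mean over its instances
        sums: dict[tuple, float] = {}
        counts: dict[tuple, int] = {}
        for i in range(ne):
            for j in range(ns):
                cell = m.codes[i][j]
                if cell:
                    key = _cell_type_key(cell)
                    sums[key] = sums.get(key, 0.0) + p.penalties[i, j]
                    counts[key] = counts.get(key, 0) + 1
        type_means = {k: sums[k] / counts[k] for k in sums}
        for i in range(ne):
            for j in range(ns):
                cell = m.codes[i][j]
                if cell:
                    out[i, j] = type_means[_cell_type_key(cell)]
        return PenaltyMatrix(list(p.event_labels), list(p.samples), out)

    # FG: supplied per-type global values, summed over a cell's codes
    if not global_means:
        raise ValueError("FG mode requires per-observation-type global means")
    for i in range(ne):
        for j in range(ns):
            cell = m.codes[i][j]
            if not cell:
                continue
            try:
                out[i, j] = sum(global_means[c] for c in cell)
            except KeyError as exc:
                raise PenaltyBuildError(
                    f"no global mean penalty supplied for observation type {exc}"
                ) from exc
    return PenaltyMatrix(list(p.event_labels), list(p.samples), out)
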