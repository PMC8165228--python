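"""Expression normalization and mutation-expression integration.

Counts are normalized between samples with the trimmed mean of M-values
(TMM): a reference sample is chosen whose upper-quartile count fraction is
closest to the cohort mean; per-sample log2 expression ratios against the
reference are trimmed (30% on the log-ratios, 5% on average abundance) and
combined in a precision-weighted mean; the resulting scaling factors are
rescaled to geometric mean 1 and fold into an effective library size for
CPM. Gene-level fold-changes are profiled against the median CPM of a
baseline sample set (by default, all other samples) with a small
pseudo-CPM offset, and rule-based mechanism flags combine hotspot-mutation
status with those fold-changes (p53 inactivation by hotspot loss of
function vs MDM2/MDM4 overexpression; MET-driven MAPK/ERK activation).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import HotspotMatch, HotspotScan
from .errors import ValidationError
from .types import Cohort, FunctionalClass, RegionClass, VariantCall

MEK_ALIASES = ("MAP2K1", "MAP2K2", "MEK", "MEK1", "MEK2")


@dataclass
class ExpressionMatrix:
    """Gene × sample raw count matrix (non-negative integers)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValidationError("duplicate gene symbols in count matrix")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample names in count matrix")
        arr = df.to_numpy()
        if arr.size and ((arr < 0).any() or not np.issubdtype(arr.dtype, np.integer)):
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValidationError("counts must be integers")
                self.counts = df.astype(int)
                arr = self.counts.to_numpy()
            if (arr < 0).any():
                raise ValidationError("counts must be non-negative")
        self.counts.index = [str(g).strip().upper() for g in self.counts.index]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def filter_low_expression(
    m: ExpressionMatrix, min_cpm: float = 1.0, min_samples: int = 2
) -> ExpressionMatrix:
    """Keep genes with raw (unnormalized) CPM >= ``min_cpm`` in at least
    ``min_samples`` samples."""
    if min_samples > len(m.samples):
        raise ValidationError("min_samples exceeds the number of samples")
    lib = m.library_sizes.astype(float)
    cpm = m.counts.div(lib, axis=1) * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return ExpressionMatrix(m.counts.loc[keep].copy())


def tmm_factors(
    m: ExpressionMatrix,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Reference sample: the one whose 75th-percentile count fraction is
    closest to the cohort mean of those fractions. For each sample, genes
    with zero counts in either the sample or the reference are dropped;
    the middle (1 − 2·logratio_trim) of log-ratios intersected with the
    middle (1 − 2·abundance_trim) of abundances enter a precision-weighted
    mean (weights are inverse asymptotic binomial variances).
    """
    counts = m.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    for j, s in enumerate(m.samples):
        if lib[j] <= 0:
            raise ValidationError(f"sample {s!r} has zero total counts")
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")

    f75 = np.array([
        np.quantile(counts[:, j], 0.75) / lib[j] for j in range(counts.shape[1])
    ])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    xr, nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        xs, ns = counts[:, j], lib[j]
        ok = (xs > 0) & (xr > 0)
        if not ok.any():
            factors[j] = 1.0
            continue
        x, r = xs[ok], xr[ok]
        logR = np.log2((x / ns) / (r / nr))
        absE = (np.log2(x / ns) + np.log2(r / nr)) / 2.0
        v = (ns - x) / (ns * x) + (nr - r) / (nr * r)
        if np.max(np.abs(logR)) < 1e-6:
            factors[j] = 1.0
            continue
        n = len(logR)
        loL = np.floor(n * logratio_trim) + 1
        hiL = n + 1 - loL
        loS = np.floor(n * abundance_trim) + 1
        hiS = n + 1 - loS
        rankR = pd.Series(logR).rank().to_numpy()
        rankE = pd.Series(absE).rank().to_numpy()
        keep = (rankR >= loL) & (rankR <= hiL) & (rankE >= loS) & (rankE <= hiS)
        if not keep.any():
            factors[j] = 1.0
            continue
        factors[j] = 2.0 ** (np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.samples, name="tmm_factor")


@dataclass
class NormalizedExpression:
    """TMM-normalized CPM: cpm(g,s) = counts(g,s)/(lib_size(s)·factor(s))·1e6."""

    cpm: pd.DataFrame
    tmm_factors: pd.Series
    library_sizes: pd.Series


def normalize(m: ExpressionMatrix, factors: pd.Series | None = None) -> NormalizedExpression:
    if factors is None:
        factors = tmm_factors(m)
    lib = m.library_sizes.astype(float)
    eff = lib * factors
    cpm = m.counts.div(eff, axis=1) * 1e6
    return NormalizedExpression(cpm=cpm, tmm_factors=factors, library_sizes=lib)


@dataclass
class FoldChangeProfile:
    """Per-sample fold-change of one gene against a baseline median CPM.

    ``FC(s) = (CPM(g,s)+pseudo) / (median CPM(g, baseline(s))+pseudo)``;
    with the default baseline, each sample is compared against the median
    of all *other* samples.
    """

    gene: str
    fold_changes: dict[str, float]
    baseline: str
    pseudo_cpm: float = 0.25
    baseline_zero: dict[str, bool] = field(default_factory=dict)

    def fc(self, sample: str) -> float | None:
        return self.fold_changes.get(sample)


def fold_change_profile(
    n: NormalizedExpression,
    gene: str,
    baseline_samples: Sequence[str] | None = None,
    pseudo_cpm: float = 0.25,
) -> FoldChangeProfile:
    """Profile a gene's fold-change across samples.

    ``baseline_samples=None`` uses, for each sample, all other samples
    (leave-one-out median); an explicit baseline set uses its median for
    every sample. Raises ``KeyError`` for an absent gene.
    """
    g = gene.strip().upper()
    if g not in n.cpm.index:
        raise KeyError(f"gene {g!r} not in the expression matrix")
    row = n.cpm.loc[g]
    samples = list(n.cpm.columns)
    if baseline_samples is not None and len(baseline_samples) == 0:
        raise ValidationError("baseline_samples must be non-empty")
    fcs: dict[str, float] = {}
    zeros: dict[str, bool] = {}
    for s in samples:
        if baseline_samples is None:
            base = [t for t in samples if t != s] or [s]
            desc = "median CPM of all other samples"
        else:
            base = list(baseline_samples)
            desc = f"median CPM of {{{', '.join(base)}}}"
        base_med = float(np.median([row[t] for t in base]))
        zeros[s] = base_med == 0.0
        fcs[s] = (float(row[s]) + pseudo_cpm) / (base_med + pseudo_cpm)
    return FoldChangeProfile(gene=g, fold_changes=fcs, baseline=desc,
                             pseudo_cpm=pseudo_cpm, baseline_zero=zeros)


@dataclass(frozen=True)
class MechanismThresholds:
    """Fold-change cutoffs for the mechanism rules (pipeline defaults; the
    underlying biology states directions, not numeric cutoffs)."""

    overexpression_fold: float = 2.0
    underexpression_fold: float = 0.5
    downstream_fold: float = 1.5
    downstream_min_genes: int = 2


Evidence = tuple[str, float | None, float, bool]  # (criterion, value, threshold, passed)


@dataclass
class MechanismFlag:
    sample_id: str
    mechanism: str  # tp53_hotspot_lof | tp53_mdm_overexpression | met_mapk_activation | none
    evidence: list[Evidence] = field(default_factory=list)
    complete: bool = True

    def __post_init__(self) -> None:
        if self.mechanism != "none" and not self.evidence:
            raise ValidationError("non-none mechanism flags need evidence")


def _fc(profiles: Mapping[str, FoldChangeProfile], gene: str, sample: str) -> float | None:
    p = profiles.get(gene.strip().upper())
    return None if p is None else p.fc(sample)


def _mek_fc(profiles: Mapping[str, FoldChangeProfile], sample: str) -> float | None:
    for alias in MEK_ALIASES:
        v = _fc(profiles, alias, sample)
        if v is not None:
            return v
    return None


def flag_mechanisms(
    cohort: Cohort | None,
    hotspot_matches: HotspotScan | Iterable[HotspotMatch],
    profiles: Mapping[str, FoldChangeProfile],
    thresholds: MechanismThresholds | None = None,
    samples: Sequence[str] | None = None,
) -> list[MechanismFlag]:
    """Apply the mutation-expression mechanism rules per sample.

    - ``tp53_hotspot_lof``: the sample carries a TP53 hotspot match AND its
      MDM2 fold-change is at or below the under-expression cutoff (a mutant
      p53 that no longer transactivates its negative regulator).
    - ``tp53_mdm_overexpression``: TP53 has no coding mutation in the sample
      but MDM2 or MDM4 is over-expressed (p53 silenced by its inhibitors).
    - ``met_mapk_activation``: MET over-expressed and at least
      ``downstream_min_genes`` of {MAPK1, MEK, MYC} above the downstream
      cutoff; no coding mutation in the downstream genes is required.

    A sample can trigger several mechanisms (one flag each); a sample that
    triggers none gets a single "none" flag. Missing profiles degrade to the
    available evidence with ``complete=False`` and a warning.
    """
    th = thresholds or MechanismThresholds()
    profiles = {g.strip().upper(): p for g, p in profiles.items()}
    matches = list(hotspot_matches)
    tp53_hotspot_samples = {
        m.variant.sample_id for m in matches if m.hotspot.gene_symbol == "TP53"
    }
    tp53_mutated_samples = set()
    if cohort is not None:
        tp53_mutated_samples = {
            v.sample_id for v in cohort.variants
            if v.gene_symbol == "TP53"
            and v.region_class == RegionClass.EXONIC
            and v.functional_class.is_nonsynonymous
        }
    if samples is None:
        some = next(iter(profiles.values()), None)
        samples = list(some.fold_changes) if some is not None else []

    required = ("TP53", "MDM2", "MDM4", "MET", "MAPK1", "MYC")
    missing = [g for g in required if g not in profiles]
    if "MEK" not in profiles and not any(a in profiles for a in MEK_ALIASES):
        missing.append("MEK")
    if missing:
        warnings.warn(f"mechanism flags computed without profiles for: {', '.join(missing)}")

    flags: list[MechanismFlag] = []
    for s in samples:
        fired = False
        mdm2 = _fc(profiles, "MDM2", s)
        mdm4 = _fc(profiles, "MDM4", s)
        met = _fc(profiles, "MET", s)
        complete = not missing

        # p53 inactivation via hotspot loss of function
        if s in tp53_hotspot_samples:
            ev: list[Evidence] = [("tp53_hotspot_match", 1.0, 1.0, True)]
            passed = mdm2 is not None and mdm2 <= th.underexpression_fold
            ev.append(("mdm2_fc_le", mdm2, th.underexpression_fold, bool(passed)))
            if passed:
                flags.append(MechanismFlag(s, "tp53_hotspot_lof", ev, complete))
                fired = True

        # p53 inactivation via MDM2/MDM4 overexpression (TP53 wild-type)
        if s not in tp53_mutated_samples and s not in tp53_hotspot_samples:
            hits = [
                ("mdm2_fc_ge", mdm2, th.overexpression_fold,
                 mdm2 is not None and mdm2 >= th.overexpression_fold),
                ("mdm4_fc_ge", mdm4, th.overexpression_fold,
                 mdm4 is not None and mdm4 >= th.overexpression_fold),
            ]
            if any(h[3] for h in hits):
                ev = [("tp53_wild_type", 1.0, 1.0, True)] + hits
                flags.append(MechanismFlag(s, "tp53_mdm_overexpression", ev, complete))
                fired = True

        # MET-driven MAPK/ERK activation
        downstream = [
            ("mapk1_fc_ge", _fc(profiles, "MAPK1", s)),
            ("mek_fc_ge", _mek_fc(profiles, s)),
            ("myc_fc_ge", _fc(profiles, "MYC", s)),
        ]
        down_ev: list[Evidence] = [
            (name, v, th.downstream_fold, v is not None and v >= th.downstream_fold)
            for name, v in downstream
        ]
        n_down = sum(1 for e in down_ev if e[3])
        met_up = met is not None and met >= th.overexpression_fold
        if met_up and n_down >= th.downstream_min_genes:
            ev = [("met_fc_ge", met, th.overexpression_fold, True)] + down_ev
            flags.append(MechanismFlag(s, "met_mapk_activation", ev, complete))
            fired = True

        if not fired:
            flags.append(MechanismFlag(s, "none", [], complete))
    return flags
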