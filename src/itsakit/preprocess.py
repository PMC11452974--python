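"""Quality filters and the sequential normalization stack.

Filtering drops proteins with Sum PEP Score < 5, fewer than 1 unique
peptide, or any missing channel value — in that order, before any
normalization.  Surviving intensities then pass through three stages
applied sequentially:

1. total-abundance: each channel is scaled so every channel sum equals
   the mean of the input channel sums (corrects loading/labeling yield);
2. IRS (Internal Reference Scaling): per-protein alignment of plexes to
   their across-plex geometric mean — the identity for a single plex;
3. TMM (trimmed mean of M-values): per-channel scale factors from the
   precision-weighted mean of doubly-trimmed log-ratios against a
   reference channel, constrained to geometric mean 1 (edgeR-convention
   defaults: 30% M-trim, 5% A-trim, upper-quartile reference pick).

All stages are per-channel positive scalings, so within-channel protein
rank order is preserved exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .quant import ProteinQuantTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_after_pep: int
    n_after_unique: int
    n_after_missing: int
    dropped: tuple[tuple[str, str], ...]  # (accession, reason)

    def __post_init__(self) -> None:
        if not (self.n_input >= self.n_after_pep >= self.n_after_unique >= self.n_after_missing):
            raise ValueError("filter counts must be non-increasing")
        if self.n_input - self.n_after_missing != len(self.dropped):
            raise ValueError("dropped list inconsistent with counts")


@dataclass(frozen=True)
class NormalizationFactors:
    """Multiplicative per-channel (or per-plex, for IRS) scale factors."""

    stage: str  # total_abundance | irs | tmm
    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError(f"{self.stage}: factors must be positive")


def filter_proteins(
    table: ProteinQuantTable,
    min_sum_pep: float = 5.0,
    min_unique: int = 1,
) -> tuple[ProteinQuantTable, FilterReport]:
    """Apply the three quality gates; thresholds are inclusive (>=).

    A row failing several gates is reported under the first one, in the
    order pep -> unique -> missing.
    """
    pep = table.data["sum_pep_score"].to_numpy(dtype=float)
    uniq = table.data["unique_peptides"].to_numpy(dtype=float)
    has_missing = np.isnan(table.abundance_matrix()).any(axis=1)
    accs = table.data["accession"].to_numpy()

    pass_pep = pep >= min_sum_pep
    pass_uniq = uniq >= min_unique
    keep = pass_pep & pass_uniq & ~has_missing

    dropped: list[tuple[str, str]] = []
    for i in np.flatnonzero(~keep):
        if not pass_pep[i]:
            reason = "pep"
        elif not pass_uniq[i]:
            reason = "unique"
        else:
            reason = "missing"
        dropped.append((str(accs[i]), reason))

    report = FilterReport(
        n_input=len(table),
        n_after_pep=int(pass_pep.sum()),
        n_after_unique=int((pass_pep & pass_uniq).sum()),
        n_after_missing=int(keep.sum()),
        dropped=tuple(dropped),
    )
    out = table.subset(
        keep, step=f"filter:pep>={min_sum_pep:g},unique>={min_unique},no-missing"
    )
    logger.info(
        "filter: %d -> %d rows (pep %d, unique %d, missing %d dropped)",
        report.n_input,
        report.n_after_missing,
        report.n_input - report.n_after_pep,
        report.n_after_pep - report.n_after_unique,
        report.n_after_unique - report.n_after_missing,
    )
    return out, report


def total_abundance_normalize(
    table: ProteinQuantTable,
) -> tuple[ProteinQuantTable, NormalizationFactors]:
    """Scale each channel so all channel sums equal the mean input channel sum."""
    mat = table.abundance_matrix()
    if np.isnan(mat).any():
        raise ValueError("total_abundance_normalize requires a missing-free table")
    sums = mat.sum(axis=0)
    zero = [l for l, s in zip(table.design.labels, sums) if s == 0]
    if zero:
        raise ValueError(f"channels with zero total abundance: {zero}")
    factors = sums.mean() / sums
    out = table.with_abundances(mat * factors, step="total_abundance")
    logger.info("total_abundance: %d rows, %d channels equalized", *mat.shape)
    return out, NormalizationFactors(
        "total_abundance", dict(zip(table.design.labels, factors.tolist()))
    )


def irs_normalize(
    tables: list[ProteinQuantTable],
) -> tuple[list[ProteinQuantTable], list[NormalizationFactors]]:
    """Align plexes per protein to the across-plex geometric mean.

    Each protein's within-plex geometric-mean abundance is rescaled to
    the geometric mean of those means across plexes, so a protein's
    overall level agrees between plexes while within-plex channel ratios
    are untouched.  With a single plex this is the identity.  Factors are
    reported per plex as the geometric mean of that plex's per-protein
    scalings.
    """
    if not tables:
        raise ValueError("need at least one plex")
    if len(tables) == 1:
        t = tables[0]
        return (
            [t.with_abundances(t.abundance_matrix(), step="irs")],
            [NormalizationFactors("irs", {t.design.plex_id: 1.0})],
        )
    common = set(tables[0].data["accession"])
    for t in tables[1:]:
        common &= set(t.data["accession"])
    if not common:
        raise ValueError("plexes share no accessions")

    aligned = []
    for t in tables:
        mask = t.data["accession"].isin(common).to_numpy()
        sub = t.subset(mask)
        sub.data.sort_values("accession", inplace=True, kind="stable")
        sub.data.reset_index(drop=True, inplace=True)
        mat = sub.abundance_matrix()
        if np.isnan(mat).any() or (mat <= 0).any():
            raise ValueError("IRS requires strictly positive, missing-free abundances")
        aligned.append((sub, mat))

    plex_log_means = np.stack([np.log(mat).mean(axis=1) for _, mat in aligned])  # (p, n)
    ref_log = plex_log_means.mean(axis=0)
    out_tables, out_factors = [], []
    for (sub, mat), logm in zip(aligned, plex_log_means):
        per_protein = np.exp(ref_log - logm)
        out_tables.append(sub.with_abundances(mat * per_protein[:, None], step="irs"))
        out_factors.append(
            NormalizationFactors(
                "irs", {sub.design.plex_id: float(np.exp(np.log(per_protein).mean()))}
            )
        )
    return out_tables, out_factors


def tmm_factors(
    table: ProteinQuantTable,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    Reference channel: the one whose upper quartile is closest to the
    mean upper quartile (ties -> lowest channel index).  Per channel,
    M = log2(channel/reference) and A = (log2 channel + log2 reference)/2
    per protein; the top and bottom ``trim_m`` of M-ranks and ``trim_a``
    of A-ranks are discarded, and the factor is 2 to the
    precision-weighted mean of the surviving M (weights 1/(1/x + 1/ref),
    the large-library limit of the edgeR asymptotic-variance weights).
    Applying the factors divides each channel by its factor.
    """
    labels = table.design.labels
    if len(labels) < 2:
        raise ValueError("TMM needs at least 2 channels")
    mat = table.abundance_matrix()
    if np.isnan(mat).any() or (mat <= 0).any():
        raise ValueError("TMM requires strictly positive, missing-free abundances")

    uq = np.percentile(mat, 75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = mat[:, ref_idx]

    raw = np.ones(len(labels))
    for j in range(len(labels)):
        if j == ref_idx:
            continue
        x = mat[:, j]
        m = np.log2(x / ref)
        a = 0.5 * np.log2(x * ref)
        keep = _double_trim_mask(m, trim_m) & _double_trim_mask(a, trim_a)
        if not keep.any():
            raise ValueError(
                "all proteins trimmed away; use smaller trim_m/trim_a"
            )
        w = 1.0 / (1.0 / x[keep] + 1.0 / ref[keep])
        raw[j] = 2.0 ** (np.sum(w * m[keep]) / np.sum(w))

    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors("tmm", dict(zip(labels, factors.tolist())))


def _double_trim_mask(values: np.ndarray, trim: float) -> np.ndarray:
    """Keep ranks in [floor(n*trim), n - floor(n*trim)); symmetric tail trim."""
    n = len(values)
    cut = int(math.floor(n * trim))
    order = np.argsort(values, kind="stable")
    keep = np.zeros(n, dtype=bool)
    keep[order[cut : n - cut]] = True
    return keep


def apply_factors(
    table: ProteinQuantTable, factors: NormalizationFactors
) -> ProteinQuantTable:
    """Divide each channel by its factor (the TMM convention)."""
    f = np.array([factors.factors[l] for l in table.design.labels])
    return table.with_abundances(table.abundance_matrix() / f, step=factors.stage)


def apply_normalization_pipeline(
    tables: ProteinQuantTable | list[ProteinQuantTable],
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[ProteinQuantTable, list[NormalizationFactors]]:
    """total-abundance -> IRS -> TMM, in that order, on filtered input.

    Accepts one plex or a list of plexes; multiple plexes are
    inner-joined on accession by the IRS stage and their channels
    concatenated (labels prefixed by plex id) before TMM.
    """
    plexes = tables if isinstance(tables, list) else [tables]
    staged, all_factors = [], []
    for t in plexes:
        norm, fac = total_abundance_normalize(t)
        staged.append(norm)
        all_factors.append(fac)
    staged, irs_facs = irs_normalize(staged)
    all_factors.extend(irs_facs)
    merged = staged[0] if len(staged) == 1 else _concat_plexes(staged)
    tmm = tmm_factors(merged, trim_m=trim_m, trim_a=trim_a)
    all_factors.append(tmm)
    out = apply_factors(merged, tmm)
    logger.info("normalization pipeline done: %d rows, stages %s",
                len(out), [f.stage for f in all_factors])
    return out, all_factors


def _concat_plexes(tables: list[ProteinQuantTable]) -> ProteinQuantTable:
    from .design import Channel, ChannelDesign

    base = tables[0]
    data = base.data[list(base.data.columns[:4])].copy()
    channels = []
    for t in tables:
        if not (t.data["accession"].to_numpy() == data["accession"].to_numpy()).all():
            raise ValueError("plexes must be aligned on accession before concatenation")
        for ch in t.design.channels:
            label = f"{t.design.plex_id}:{ch.label}"
            channels.append(Channel(label, ch.condition))
            data[label] = t.data[ch.label].to_numpy()
    design = ChannelDesign("merged", tuple(channels))
    prov = list(base.provenance) + ["merge_plexes"]
    return ProteinQuantTable(data, design, prov)
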