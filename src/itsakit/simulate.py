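"""Synthetic iTSA experiments with known ground truth.

The generative model mirrors what a single-temperature thermal-challenge
TMT experiment measures.  Each protein has a log-normal base abundance
(soluble amount surviving the heat step in vehicle).  A measured reporter
intensity is

    control channel:  base * loading * noise
    treated channel:  base * shift * loading * noise

where ``shift`` is the ligand-stabilization fold change (1 for
non-targets), ``loading`` is a per-channel multiplicative loading/labeling
factor shared by all proteins, and ``noise`` is multiplicative log-normal
with a fixed coefficient of variation — the standard error model for TMT
reporter ions, whose spread is stable on the log scale.  Missing values
are left-censored: the probability of a dropped measurement decays
logistically with log-intensity, as in real MS data where low-abundance
ions fall below the identification/quantification limit.

Randomness is organised as one named substream per protein (plus one for
plex-level draws), all derived from a single seed, so enlarging the
panel leaves the earlier rows' measurements bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import ChannelDesign, default_10plex
from .quant import META_COLUMNS, ProteinQuantTable
from .pooling import BindingMap


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one simulated 10-plex iTSA experiment.

    Defaults describe the panel used throughout the package's own
    calibration: 3000 proteins with 50 spiked targets at a fixed 1.6-fold
    stabilization, 10% reporter CV, mild channel loading imbalance
    (log-normal, sd 0.1), 2% left-censored missingness and 5% of rows
    drawn below the Sum-PEP-Score quality gate.  The thermal challenge
    metadata (53 degC for 3 min) is carried as free text provenance only.
    """

    n_proteins: int = 3000
    n_targets: int = 50
    shift: float = 1.6                 # linear FC applied to targets, >= 1
    cv: float = 0.10                   # reporter-ion coefficient of variation
    channel_loading_sd: float = 0.1    # sd of log-normal per-channel loading
    missing_rate: float = 0.02         # mean probability of a missing cell
    pep_fail_rate: float = 0.05        # fraction of rows with Sum PEP Score < 5
    design: ChannelDesign = field(default_factory=default_10plex)
    base_log_mean: float = math.log(1e6)
    base_log_sd: float = 1.5
    temperature_c: float = 53.0
    duration_min: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if not 0 <= self.n_targets <= self.n_proteins:
            raise ValueError("n_targets must be in [0, n_proteins]")
        if self.shift < 1:
            raise ValueError("shift must be >= 1 (stabilization only)")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for name in ("missing_rate", "pep_fail_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Which accessions were spiked, and by how much (linear FC >= 1)."""

    target_accessions: frozenset[str]
    shifts: dict[str, float] = field(default_factory=dict)

    def shift_of(self, accession: str) -> float:
        return self.shifts.get(accession, 1.0)


def _plex_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))


def _protein_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index + 1,)))


def generate_itsa_experiment(config: SynthConfig) -> tuple[ProteinQuantTable, GroundTruth]:
    """Draw one quant table plus its ground truth; same config => same bits."""
    n, labels = config.n_proteins, config.design.labels
    n_chan = len(labels)
    treated_mask = np.array([c.condition == "treated" for c in config.design.channels])
    sigma_noise = math.sqrt(math.log(1.0 + config.cv**2))

    plex = _plex_rng(config.seed)
    if config.channel_loading_sd > 0:
        loading = plex.lognormal(mean=0.0, sigma=config.channel_loading_sd, size=n_chan)
    else:
        loading = np.ones(n_chan)
    target_idx = np.sort(plex.choice(n, size=config.n_targets, replace=False))
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True

    accs = np.array([f"P{i:05d}" for i in range(n)])
    genes = np.array([f"GENE{i}" for i in range(n)])
    mat = np.empty((n, n_chan))
    pep = np.empty(n)
    uniq = np.empty(n, dtype=int)

    for i in range(n):
        rng = _protein_rng(config.seed, i)
        base = rng.lognormal(mean=config.base_log_mean, sigma=config.base_log_sd)
        if sigma_noise > 0:
            noise = rng.lognormal(mean=-sigma_noise**2 / 2, sigma=sigma_noise, size=n_chan)
        else:
            noise = np.ones(n_chan)
        shift = config.shift if is_target[i] else 1.0
        values = base * loading * noise
        values[treated_mask] *= shift
        # left-censored missingness: logistic in log-intensity, centred on the
        # panel log-mean so the average cell-missing probability ~= missing_rate
        if config.missing_rate > 0:
            z = (np.log(values) - config.base_log_mean) / config.base_log_sd
            p_miss = np.minimum(0.95, 2.0 * config.missing_rate * expit(-z))
            values[rng.random(n_chan) < p_miss] = np.nan
        if rng.random() < config.pep_fail_rate:
            pep[i] = rng.uniform(0.0, 5.0)
        else:
            pep[i] = 5.0 + rng.exponential(30.0)
        uniq[i] = 1 + rng.poisson(7.0)
        mat[i] = values

    data = pd.DataFrame(
        {
            "accession": accs,
            "gene_symbol": genes,
            "sum_pep_score": pep,
            "unique_peptides": uniq,
        }
    )
    for j, label in enumerate(labels):
        data[label] = mat[:, j]
    prov = [
        f"simulated:iTSA {config.temperature_c:g}degC/{config.duration_min:g}min "
        f"seed={config.seed} n={n} targets={config.n_targets} shift={config.shift:g}"
    ]
    table = ProteinQuantTable(data, config.design, provenance=prov)
    truth = GroundTruth(
        target_accessions=frozenset(accs[target_idx]),
        shifts={a: config.shift for a in accs[target_idx]},
    )
    return table, truth


def generate_null_experiment(config: SynthConfig) -> tuple[ProteinQuantTable, GroundTruth]:
    """The same draw with no spiked targets (for false-positive calibration)."""
    return generate_itsa_experiment(replace(config, n_targets=0))


def generate_binding_map(
    molecules: Sequence[str],
    targets: Sequence[str],
    density: float,
    seed: int,
) -> BindingMap:
    """Random bipartite molecule -> target ground truth for pooled screens."""
    if not molecules or not targets:
        raise ValueError("molecules and targets must be nonempty")
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = {
        (m, t)
        for m in molecules
        for t in targets
        if rng.random() < density
    }
    return BindingMap(frozenset(edges))
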