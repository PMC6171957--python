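"""Synthetic proteomes with planted composition structure.

Three coupled generators emulate the statistical structure the analysis
assumes, so every stage of the pipeline can be exercised end to end without
real data:

* a proteome whose residues are drawn from background frequencies, with a
  configurable fraction of proteins carrying one planted domain locally
  enriched for a single residue;
* a log-normal per-protein property whose log-median shifts by a per-residue
  effect for proteins whose planted domain reaches a composition threshold
  (positive shifts for A/G/V, negative for the other residues by default,
  mirroring the trends seen for translation efficiency, abundance and
  half-life in real proteomes);
* a membership set (stress-granule / P-body style) that includes enriched
  proteins with a set sensitivity and others at one minus the specificity.

Planted domains are probabilistic: each domain position carries the target
residue with probability ``rho``, so realized compositions straddle bin
edges and exercise the exact-integer binning logic. All three generators
are deterministic functions of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from compscan.proteome_io import CANONICAL_AA, ProteinRecord, PropertyTable

# approximate S. cerevisiae translated-proteome residue frequencies; a
# yeast-like default, not a claim about any specific release
YEAST_LIKE_FREQUENCIES: dict[str, float] = {
    "A": 0.0551, "C": 0.0126, "D": 0.0586, "E": 0.0655, "F": 0.0441,
    "G": 0.0498, "H": 0.0217, "I": 0.0655, "K": 0.0734, "L": 0.0957,
    "M": 0.0208, "N": 0.0614, "P": 0.0438, "Q": 0.0393, "R": 0.0445,
    "S": 0.0896, "T": 0.0589, "V": 0.0556, "W": 0.0104, "Y": 0.0337,
}

_POSITIVE_RESIDUES = frozenset("AGV")


def default_effect_signs() -> dict[str, float]:
    """Per-residue signed log-scale effects: +log 2 for A/G/V, -log 2 else."""
    return {
        aa: (math.log(2) if aa in _POSITIVE_RESIDUES else -math.log(2))
        for aa in CANONICAL_AA
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic proteome.

    Attributes
    ----------
    n_proteins : number of proteins.
    length_range : (min, max) of the uniform length distribution.
    background : residue -> frequency; must sum to 1.
    planted_residue : the single residue enriched in planted domains.
    pi : fraction of proteins receiving a planted domain.
    domain_length : planted domain length d.
    rho : per-position probability of the target residue inside the domain.
    beta : residue -> signed log-scale property shift for proteins whose
        planted domain's realized composition reaches ``tau``.
    sigma : log-scale noise standard deviation.
    tau : composition threshold coupling enrichment to effects/membership.
    sensitivity, specificity : membership inclusion probabilities.
    seed : master seed; every generator derives its stream from it.
    """

    n_proteins: int = 2000
    length_range: tuple[int, int] = (50, 400)
    background: dict[str, float] = field(default_factory=lambda: dict(YEAST_LIKE_FREQUENCIES))
    planted_residue: str = "N"
    pi: float = 0.1
    domain_length: int = 30
    rho: float = 0.5
    beta: dict[str, float] = field(default_factory=default_effect_signs)
    sigma: float = 0.5
    mu: float = 0.0
    tau: float = 0.35
    sensitivity: float = 0.8
    specificity: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pi <= 1:
            raise ValueError("pi must lie in [0, 1]")
        if self.domain_length > self.length_range[0]:
            raise ValueError("domain_length must not exceed the minimum protein length")
        if not self.rho > self.background.get(self.planted_residue, 0.0):
            raise ValueError("rho must exceed the background frequency of the residue")
        if self.rho > 1:
            raise ValueError("rho must be <= 1")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")


def generate_proteome(cfg: SyntheticConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Draw the proteome and return it with its ground truth.

    Ground-truth columns: protein_id, planted (bool), residue, start, end
    (1-based inclusive), domain_count (realized target-residue count inside
    the domain), domain_length. Realized composition is the exact integer
    pair (domain_count, domain_length).
    """
    rng = np.random.default_rng(cfg.seed)
    residues = np.array(list(cfg.background))
    probs = np.array([cfg.background[aa] for aa in residues])
    probs = probs / probs.sum()
    lo, hi = cfg.length_range
    truth_rows = []
    proteome: list[ProteinRecord] = []
    for i in range(cfg.n_proteins):
        pid = f"SYN{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(residues, size=length, p=probs)
        planted = bool(rng.random() < cfg.pi)
        start = end = 0
        count = 0
        if planted:
            d = cfg.domain_length
            pos = int(rng.integers(0, length - d + 1))
            hits = rng.random(d) < cfg.rho
            domain = np.where(hits, cfg.planted_residue, rng.choice(residues, size=d, p=probs))
            seq[pos : pos + d] = domain
            count = int(np.sum(domain == cfg.planted_residue))
            start, end = pos + 1, pos + d
        proteome.append(ProteinRecord(pid, "".join(seq)))
        truth_rows.append(
            {
                "protein_id": pid,
                "planted": planted,
                "residue": cfg.planted_residue if planted else "",
                "start": start,
                "end": end,
                "domain_count": count,
                "domain_length": cfg.domain_length if planted else 0,
            }
        )
    return proteome, pd.DataFrame(truth_rows)


def _enriched_mask(truth: pd.DataFrame, cfg: SyntheticConfig) -> pd.Series:
    # tau as an integer percent keeps the comparison exact at bin edges
    tau_pct = round(100 * cfg.tau)
    return truth["planted"] & (
        100 * truth["domain_count"] >= tau_pct * truth["domain_length"]
    )


def generate_properties(
    truth: pd.DataFrame, cfg: SyntheticConfig, name: str = "synthetic_property"
) -> PropertyTable:
    """Log-normal property values with composition-linked median shifts.

    value_i = exp(mu + beta_X * 1[planted X-domain with realized composition
    >= tau] + eps_i), eps_i ~ Normal(0, sigma^2). The property stream is
    seeded independently of the proteome stream (seed + 1).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    enriched = _enriched_mask(truth, cfg).to_numpy()
    beta = cfg.beta.get(cfg.planted_residue, 0.0)
    eps = rng.normal(0.0, cfg.sigma, size=len(truth))
    log_values = cfg.mu + beta * enriched.astype(float) + eps
    values = dict(zip(truth["protein_id"], np.exp(log_values)))
    return PropertyTable(name=name, values=values, units="arbitrary")


def generate_membership(truth: pd.DataFrame, cfg: SyntheticConfig) -> set[str]:
    """Membership set correlated with planted enrichment.

    Enriched proteins enter with probability ``sensitivity``; all others
    with probability ``1 - specificity``. Seeded from seed + 2.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    enriched = _enriched_mask(truth, cfg).to_numpy()
    u = rng.random(len(truth))
    include = np.where(enriched, u < cfg.sensitivity, u < 1.0 - cfg.specificity)
    return set(truth.loc[include, "protein_id"])


def generate_bundle(cfg: SyntheticConfig):
    """Proteome + truth + property table + membership set, all from cfg.seed."""
    proteome, truth = generate_proteome(cfg)
    prop = generate_properties(truth, cfg)
    members = generate_membership(truth, cfg)
    return proteome, truth, prop, members
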