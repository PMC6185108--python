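"""Synthetic glycoproteome with ground-truth occupancy and degradation.

The generator emulates a paired two-genotype label-free MS study of a mild
N-glycosylation defect:

* a proteome in which a fraction of proteins carry 1-16 glycosylation sites
  (1 + negative binomial multiplicity law) with sampled sequon classes and
  -2 contexts, embedded in random backbones that contain no other Asn, so the
  placed sites are exactly the scannable ones;
* per-site transfer efficiency ``e`` set by sequon class (NxT > NxS >>
  non-canonical, +0.02 for an aromatic -2 residue, capped at 0.995);
* a global glycosylation stress ``s`` that lowers mutant occupancy as
  ``o_mut = e * max(0, 1 - kappa * s * (1 - e))`` — inefficient sequons lose
  disproportionally more occupancy, and the loss clips at fully unoccupied;
* protein-level degradation driven by the expected number of newly
  unoccupied sites, ``r = exp(-lambda * sum(o_ctrl - o_mut))`` — multiplicity
  enters only through that sum, so highly glycosylated proteins are degraded
  more under the same per-site loss;
* log-normal intensities with shared litter (pair) effects, replicate noise,
  a fixed per-peptide ionization offset shared between the glycosylated and
  unmodified form of a site, and missing-not-at-random dropout: each cell is
  observed with probability ``logistic((log2 I - tau) / omega)``. A site with
  zero occupancy yields MISSING (an absent species cannot ionize), never 0.

Everything is drawn from one ``numpy`` generator seeded by ``SimConfig.seed``,
so a config reproduces its dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    CONTROL,
    MUTANT,
    ProteinRecord,
    QuantMatrix,
    SampleDesign,
    SiteKey,
)
from .sequons import AROMATIC, NON_CANONICAL, NXS, NXT, GlycoSite, classify_site

#: backbone alphabet: the 20 amino acids minus Asn, so that no sequon can
#: arise outside the placed sites
BACKBONE = np.array(list("ACDEFGHIKLMPQRSTVWY"))
_X_RESIDUES = np.array(list("ACDEFGHIKLMQRSTVWY"))  # +1: no Pro, no Asn
_NC_PLUS2 = np.array(list("ACDEGHIKLMQV"))  # +2 of a non-canonical sequon
_AROMATIC_ARR = np.array(list("FYHW"))
_NON_AROMATIC_M2 = np.array(list("ACDEGIKLMPQRSTV"))  # -2, non-aromatic, no Asn

MULTIPLICITY_CAP = 16


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiment (defaults = the emulated
    design: 2 genotypes x 4 paired replicates, mild stress)."""

    n_proteins: int = 2000
    glycoprotein_fraction: float = 0.4
    multiplicity_mean: float = 1.8  # negative-binomial mean of (multiplicity - 1)
    multiplicity_dispersion: float = 1.0
    sequon_class_probs: dict = field(
        default_factory=lambda: {NXT: 0.45, NXS: 0.45, NON_CANONICAL: 0.10}
    )
    minus2_aromatic_prob: float = 0.15
    efficiency: dict = field(
        default_factory=lambda: {NXT: 0.98, NXS: 0.92, NON_CANONICAL: 0.70}
    )
    aromatic_bonus: float = 0.02
    efficiency_cap: float = 0.995
    stress: float = 0.5  # s in [0, 1]
    sensitivity: float = 3.0  # kappa >= 0
    degradation_rate: float = 1.0  # lambda >= 0
    abundance_log2_mean: float = 20.0
    abundance_log2_sd: float = 2.0
    replicate_sd: float = 0.25
    pair_effect_sd: float = 0.3
    site_ionization_log2_sd: float = 1.0
    detection_midpoint: float = 18.0  # tau
    detection_width: float = 1.0  # omega
    n_control: int = 4
    n_mutant: int = 4
    known_site_fraction: float = 0.75  # share of true sites put on the known list
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.glycoprotein_fraction,
            self.minus2_aromatic_prob,
            self.known_site_fraction,
            *self.sequon_class_probs.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.isclose(sum(self.sequon_class_probs.values()), 1.0):
            raise ValueError("sequon class probabilities must sum to 1")
        if not 0 <= self.stress <= 1:
            raise ValueError("stress must lie in [0, 1]")
        if self.sensitivity < 0 or self.degradation_rate < 0:
            raise ValueError("sensitivity and degradation_rate must be >= 0")
        if self.n_proteins < 1 or self.n_control < 1 or self.n_mutant < 1:
            raise ValueError("n_proteins and group sizes must be >= 1")
        if self.detection_width <= 0 or self.replicate_sd < 0:
            raise ValueError("detection_width must be > 0 and noise sds >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class SimTruth:
    """Ground truth: per-site occupancies and per-protein degradation.

    ``sites`` columns: protein_id, position, sequon_class, minus2_aromatic,
    efficiency, o_ctrl, o_mut (indexed by feature id "protein:position").
    ``proteins`` columns: is_glycoprotein, multiplicity, delta_u (expected
    increase in unoccupied sites), degradation_r (indexed by protein_id).
    """

    sites: pd.DataFrame
    proteins: pd.DataFrame


def site_efficiency(config: SimConfig, sequon_class: str, aromatic: bool) -> float:
    e = config.efficiency[sequon_class] + (config.aromatic_bonus if aromatic else 0.0)
    return min(e, config.efficiency_cap)


def mutant_occupancy(config: SimConfig, e: float) -> float:
    """o_mut = e * max(0, 1 - kappa * s * (1 - e)), clipped at zero."""
    return e * max(0.0, 1.0 - config.sensitivity * config.stress * (1.0 - e))


def generate_proteome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[GlycoSite], SimTruth]:
    """Sample a proteome, its true glycosites and the occupancy/degradation truth."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_proteins

    is_glyco = rng.random(n) < config.glycoprotein_fraction
    disp = config.multiplicity_dispersion
    nb = rng.negative_binomial(disp, disp / (disp + config.multiplicity_mean), size=n)
    mult = np.where(is_glyco, np.minimum(1 + nb, MULTIPLICITY_CAP), 0)
    lengths = 100 + 50 * mult + rng.integers(0, 300, size=n)

    class_names = list(config.sequon_class_probs)
    class_p = np.array([config.sequon_class_probs[c] for c in class_names])

    proteins: list[ProteinRecord] = []
    sites: list[GlycoSite] = []
    site_rows: list[dict] = []
    protein_rows: list[dict] = []
    for i in range(n):
        pid = f"SP{i:05d}"
        length = int(lengths[i])
        seq = rng.choice(BACKBONE, size=length)
        m = int(mult[i])
        delta_u = 0.0
        if m:
            n_slots = (length - 10) // 5
            slot = np.sort(rng.choice(n_slots, size=m, replace=False))
            pos = 5 * slot + 3  # 1-based Asn positions, windows 5 apart
            classes = rng.choice(len(class_names), size=m, p=class_p)
            aromatic = rng.random(m) < config.minus2_aromatic_prob
            for j in range(m):
                p = int(pos[j])
                cls = class_names[int(classes[j])]
                seq[p - 1] = "N"
                seq[p] = rng.choice(_X_RESIDUES)
                if cls == NXT:
                    seq[p + 1] = "T"
                elif cls == NXS:
                    seq[p + 1] = "S"
                else:
                    seq[p + 1] = rng.choice(_NC_PLUS2)
                seq[p - 3] = (
                    rng.choice(_AROMATIC_ARR) if aromatic[j] else rng.choice(_NON_AROMATIC_M2)
                )
            record = ProteinRecord(pid, "".join(seq))
            for j in range(m):
                p = int(pos[j])
                cls = class_names[int(classes[j])]
                e = site_efficiency(config, cls, bool(aromatic[j]))
                o_ctrl = e
                o_mut = mutant_occupancy(config, e)
                delta_u += o_ctrl - o_mut
                site = classify_site(record, SiteKey(pid, p))
                sites.append(site)
                site_rows.append(
                    {
                        "feature_id": str(site.key),
                        "protein_id": pid,
                        "position": p,
                        "sequon_class": site.sequon_class,
                        "minus2_aromatic": bool(aromatic[j]),
                        "efficiency": e,
                        "o_ctrl": o_ctrl,
                        "o_mut": o_mut,
                    }
                )
        else:
            record = ProteinRecord(pid, "".join(seq))
        proteins.append(record)
        protein_rows.append(
            {
                "protein_id": pid,
                "is_glycoprotein": bool(is_glyco[i]),
                "multiplicity": m,
                "delta_u": delta_u,
                "degradation_r": float(np.exp(-config.degradation_rate * delta_u)),
            }
        )
    site_df = pd.DataFrame(
        site_rows,
        columns=[
            "feature_id",
            "protein_id",
            "position",
            "sequon_class",
            "minus2_aromatic",
            "efficiency",
            "o_ctrl",
            "o_mut",
        ],
    ).set_index("feature_id")
    protein_df = pd.DataFrame(protein_rows).set_index("protein_id")
    return proteins, sites, SimTruth(sites=site_df, proteins=protein_df)


def default_design(config: SimConfig) -> list[SampleDesign]:
    return [
        *(SampleDesign(f"C{i + 1}", CONTROL, i + 1) for i in range(config.n_control)),
        *(SampleDesign(f"M{i + 1}", MUTANT, i + 1) for i in range(config.n_mutant)),
    ]


@dataclass
class SimulatedExperiment:
    """The three quantification tables plus the latent variables behind them."""

    design: list[SampleDesign]
    protein_matrix: QuantMatrix
    glyco_matrix: QuantMatrix
    unmodified_matrix: QuantMatrix
    abundance_log2: pd.Series  # per protein
    ionization_offset: pd.Series  # per site feature id


def simulate_quant(
    config: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator,
) -> SimulatedExperiment:
    """Draw the total-proteome, glycosite and unmodified-peptide tables.

    Per sample, protein log2 intensity = abundance + pair effect (shared by
    the two members of a litter pair) + replicate noise, with mutants shifted
    by log2(degradation r). A glycosite adds log2(occupancy) plus its fixed
    ionization offset; the unmodified peptide of the same site uses
    log2(1 - occupancy) and the same offset. Observation is Bernoulli with
    probability logistic((log2 I - tau) / omega); zero occupancy is MISSING
    by construction.
    """
    design = default_design(config)
    protein_ids = list(truth.proteins.index)
    n_prot = len(protein_ids)
    n_samples = len(design)
    genotype_mut = np.array([s.genotype == MUTANT for s in design])
    pair_idx = np.array([s.pair_id - 1 for s in design])
    n_pairs = max(s.pair_id for s in design)

    abundance = rng.normal(config.abundance_log2_mean, config.abundance_log2_sd, n_prot)
    pair_fx = rng.normal(0.0, config.pair_effect_sd, (n_prot, n_pairs))
    log2_r = np.log2(truth.proteins["degradation_r"].to_numpy())

    base = (
        abundance[:, None]
        + pair_fx[:, pair_idx]
        + np.where(genotype_mut[None, :], log2_r[:, None], 0.0)
    )

    def observe(log2_i: np.ndarray, forced_missing: np.ndarray | None = None) -> np.ndarray:
        p_detect = 1.0 / (
            1.0 + np.exp(-(log2_i - config.detection_midpoint) / config.detection_width)
        )
        detected = rng.random(log2_i.shape) < p_detect
        raw = np.exp2(log2_i)
        raw[~detected] = np.nan
        if forced_missing is not None:
            raw[forced_missing] = np.nan
        return raw

    protein_vals = observe(base + rng.normal(0.0, config.replicate_sd, (n_prot, n_samples)))
    protein_matrix = QuantMatrix(
        pd.DataFrame(protein_vals, index=protein_ids, columns=[s.sample_id for s in design]),
        design,
        "protein",
    )

    site_ids = list(truth.sites.index)
    n_sites = len(site_ids)
    prot_pos = {pid: k for k, pid in enumerate(protein_ids)}
    site_prot = np.array([prot_pos[p] for p in truth.sites["protein_id"]])
    offsets = rng.normal(0.0, config.site_ionization_log2_sd, n_sites)
    o_ctrl = truth.sites["o_ctrl"].to_numpy()
    o_mut = truth.sites["o_mut"].to_numpy()
    occ = np.where(genotype_mut[None, :], o_mut[:, None], o_ctrl[:, None])
    unocc = 1.0 - occ

    # The glyco experiment profiles *distinct animals*: its biological
    # (litter) effects are drawn independently per sample rather than shared
    # within a pair, which is also why that branch is tested unpaired. The
    # unmodified-peptide table belongs to the total-proteome experiment and
    # keeps the paired animals' effects.
    glyco_bio = rng.normal(0.0, config.pair_effect_sd, (n_prot, n_samples))
    glyco_base = (
        abundance[:, None]
        + glyco_bio
        + np.where(genotype_mut[None, :], log2_r[:, None], 0.0)
    )[site_prot] + offsets[:, None]
    unmod_base = base[site_prot] + offsets[:, None]
    with np.errstate(divide="ignore"):
        glyco_log2 = glyco_base + np.log2(occ)
        unmod_log2 = unmod_base + np.log2(unocc)
    glyco_noise = rng.normal(0.0, config.replicate_sd, (n_sites, n_samples))
    unmod_noise = rng.normal(0.0, config.replicate_sd, (n_sites, n_samples))
    sample_cols = [s.sample_id for s in design]
    glyco_vals = observe(glyco_log2 + glyco_noise, forced_missing=(occ == 0))
    unmod_vals = observe(unmod_log2 + unmod_noise, forced_missing=(unocc == 0))
    glyco_matrix = QuantMatrix(
        pd.DataFrame(glyco_vals, index=site_ids, columns=sample_cols), design, "glycosite"
    )
    unmodified_matrix = QuantMatrix(
        pd.DataFrame(unmod_vals, index=site_ids, columns=sample_cols),
        design,
        "unmodified_peptide",
    )
    return SimulatedExperiment(
        design=design,
        protein_matrix=protein_matrix,
        glyco_matrix=glyco_matrix,
        unmodified_matrix=unmodified_matrix,
        abundance_log2=pd.Series(abundance, index=protein_ids, name="abundance_log2"),
        ionization_offset=pd.Series(offsets, index=site_ids, name="ionization_offset"),
    )


@dataclass
class SimulatedDataset:
    proteins: list[ProteinRecord]
    sites: list[GlycoSite]
    truth: SimTruth
    experiment: SimulatedExperiment
    known_sites: set[SiteKey]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """One-call generator: proteome + truth + quant tables + known-site list.

    The known-site list is a random subsample of the true sites, shipped so a
    run can exercise novel-site calling against an incomplete atlas.
    """
    rng = np.random.default_rng(config.seed)
    proteins, sites, truth = generate_proteome(config, rng)
    experiment = simulate_quant(config, truth, rng)
    keep = rng.random(len(sites)) < config.known_site_fraction
    known = {site.key for site, k in zip(sites, keep) if k}
    return SimulatedDataset(proteins, sites, truth, experiment, known)


def informative_counterparts(
    truth: SimTruth,
    experiment: SimulatedExperiment,
    config: SimConfig,
    margin: float = 2.0,
) -> pd.Series:
    """Sites whose unmodified peptide is confidently observable where present
    and confidently absent where not.

    A counterpart is *informative* when its expected log2 intensity (protein
    abundance + degradation shift + log2(1 - occupancy) + ionization offset,
    noise-free) clears the detection midpoint by ``margin`` detection widths
    in mutants and stays the same margin below it in controls. Only such
    counterparts can witness an occupancy loss as an exclusive detection
    pattern; the recovery diagnostics condition on this set.
    """
    tau, omega = config.detection_midpoint, config.detection_width
    abundance = experiment.abundance_log2[truth.sites["protein_id"]].to_numpy()
    offset = experiment.ionization_offset[truth.sites.index].to_numpy()
    log2_r = np.log2(
        truth.proteins.loc[truth.sites["protein_id"], "degradation_r"].to_numpy()
    )
    with np.errstate(divide="ignore"):
        mut_expected = abundance + log2_r + np.log2(1.0 - truth.sites["o_mut"].to_numpy()) + offset
        ctrl_expected = abundance + np.log2(1.0 - truth.sites["o_ctrl"].to_numpy()) + offset
    ok = (mut_expected >= tau + margin * omega) & (ctrl_expected <= tau - margin * omega)
    return pd.Series(ok, index=truth.sites.index, name="informative_counterpart")
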