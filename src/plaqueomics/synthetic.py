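"""Synthetic carotid-plaque cohorts with planted molecular structure.

The generator emulates the statistical skeleton of an endarterectomy discovery
cohort: 105 plaque cores (60 calcified / 46 noncalcified, 36 symptomatic / 69
asymptomatic, 29 female / 76 male), three extraction fractions (SDS cellular,
NaCl soluble matrisome, GuHCl core matrisome), anti-correlated inflammation and
calcification axes (r = -0.6), a sex-linked proteoglycan block anti-correlated
with estradiol, four molecular phenotype clusters, and cardiovascular event
hazards driven by a four-protein signature (CNN1, PROC, SERPH, CSPG2).

Design notes
------------
* Two latent axes (inflammation, calcification) are drawn from an exact
  bivariate normal with the configured correlation; signature *anchor* proteins
  load on these axes.  Group labels are derived from the axes by top-k ranking
  (calcified = largest calcification propensities, symptomatic = largest
  inflammation scores), so the planted axis correlation is untouched by
  labelling and the realized group contrasts are genuine axis effects.
* Phenotype clusters shift dedicated *cluster-marker* blocks, not the anchor
  blocks, so axis-recovery properties and phenotype-recovery properties are
  separable.  Cluster 3 is the calcified / proteoglycan-high, female-enriched
  phenotype: the female and calcified propensities carry a cluster-3 bonus.
* Ground truth records the *realized* noise-free group-mean difference per
  protein and contrast — exact planted log2FC values for the differential
  module under this label mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import (
    AbundanceMatrix,
    AnnotationTable,
    Fraction,
    SampleMetadata,
    write_abundance_table,
    write_annotation_table,
    write_sample_metadata,
)

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study",
           "simulate_risk_panel", "write_study"]

# Signature anchor proteins per fraction (uniprot-style short ids).
ANCHORS: dict[Fraction, dict[str, list[str]]] = {
    Fraction.SDS: {
        "inflammation": ["S10A8", "S10A9", "PERM", "MMP9", "TIMP1", "DEF1",
                         "FRIL", "FRIH", "CD14"],
        "smc": ["ACTA", "TAGL", "CNN1", "CALD1"],
    },
    Fraction.NACL: {
        "inflammation": ["S10A8", "S10A9", "PERM", "MMP9", "TIMP1", "DEF1",
                         "CATD", "CATB", "CD44"],
        "calcification": ["FETUA", "OSTP", "MGP", "GAS6", "SPRC", "OSTC"],
        "proteoglycan": ["HPLN1", "SODE"],
    },
    Fraction.GUHCL: {
        "inflammation": ["S10A8", "S10A9", "PERM", "TIMP1", "CATD", "CATB",
                         "CD44", "TRFL"],
        "calcification": ["FETUA", "OSTP", "MGP", "GAS6", "FA9", "FA10",
                          "PROC", "PROZ", "SPRC", "OSTC", "FA7", "PROS"],
        "proteoglycan": ["CSPG2", "PGCA", "HPLN1", "HPLN3", "SODE"],
        "structural_ecm": ["CO1A1", "CO1A2", "CO3A1", "SERPH"],
    },
}

# Cluster-marker blocks: which phenotype axis shifts which fraction's markers.
MARKER_AXES: dict[Fraction, list[str]] = {
    Fraction.SDS: ["inflammation", "smc"],
    Fraction.NACL: ["calcification"],
    Fraction.GUHCL: ["structural_ecm", "proteoglycan", "calcification"],
}

# Phenotype centroids over the five marker axes
# (rows: clusters 0..3; cols: inflammation, smc, structural_ecm, proteoglycan,
#  calcification).  Cluster 0: inflamed ECM-poor; 1: SMC-rich fibrous;
#  2: structural-ECM high; 3: calcified proteoglycan-rich (female-enriched).
CENTROIDS = pd.DataFrame(
    [
        [1.0, -0.5, -1.0, -0.5, 0.0],
        [0.0, 1.0, 0.5, 0.0, -0.5],
        [-0.5, 0.0, 1.0, 0.0, 0.0],
        [-0.5, -0.5, 0.0, 1.0, 1.0],
    ],
    columns=["inflammation", "smc", "structural_ecm", "proteoglycan",
             "calcification"],
)

#: log hazard-ratio per SD of noise-free abundance for the prognostic quartet
DEFAULT_HAZARD_COEFS = {"CNN1": -0.45, "PROC": 0.45, "SERPH": -0.45,
                        "CSPG2": 0.45}


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the study conditions."""

    seed: int = 0
    n_core_samples: int = 105
    n_proteins: Mapping[str, int] = field(
        default_factory=lambda: {"SDS": 1459, "NaCl": 283, "GuHCl": 286})
    group_counts: Mapping[str, int] = field(
        default_factory=lambda: {"calcified": 60, "symptomatic": 36,
                                 "female": 29})
    axis_correlation: float = -0.6
    loading: float = 1.0          # latent-axis loading of anchors (log2 units/SD)
    effect_size: float = 0.8      # planted female shift on proteoglycan anchors
    phenotype_separation: float = 3.0   # marker shift, units of noise_sd
    n_phenotypes: int = 4
    phenotype_props: tuple[float, ...] = (0.30, 0.24, 0.22, 0.24)
    markers_per_axis: int = 40
    extra_axis_members: int = 0   # unnamed extra signature members per block
    noise_sd: float = 0.5
    missing_rate: float = 0.05
    intensity_dependent_missing: bool = False
    hazard_baseline: float = 0.045      # events / patient-year
    hazard_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_COEFS))
    followup_horizon: float = 9.0       # administrative censoring, years
    dropout_rate: float = 0.03          # exponential dropout, per year
    estradiol_slope: float = -0.5       # per SD of proteoglycan latent, females
    periphery: bool = False             # optional paired periphery samples
    periphery_attenuation: float = 0.4

    def validate(self) -> None:
        for name, count in self.group_counts.items():
            if not 0 <= count <= self.n_core_samples:
                raise ValueError(
                    f"group count {name}={count} exceeds cohort size "
                    f"{self.n_core_samples}")
        if not -1 < self.axis_correlation < 1:
            raise ValueError("axis_correlation must lie in (-1, 1)")
        if self.noise_sd < 0 or self.missing_rate < 0:
            raise ValueError("rates must be >= 0")
        if abs(sum(self.phenotype_props) - 1) > 1e-9:
            raise ValueError("phenotype proportions must sum to 1")


@dataclass
class StudyTruth:
    """Planted ground truth of a simulated cohort."""

    latent: pd.DataFrame                    # samples x latent axes
    log2fc: dict[str, pd.DataFrame]         # fraction -> protein x contrast
    phenotype: pd.Series                    # sample -> planted cluster id
    hazard_lp: pd.Series                    # linear predictor of the hazard
    blocks: dict[str, dict[str, list[str]]]  # fraction -> tag -> protein ids


@dataclass
class SimulatedStudy:
    matrices: dict[str, AbundanceMatrix]
    metadata: SampleMetadata
    annotation: AnnotationTable
    truth: StudyTruth
    config: SimulationConfig


def _phenotype_sizes(cfg: SimulationConfig) -> list[int]:
    raw = [p * cfg.n_core_samples for p in cfg.phenotype_props]
    sizes = [int(np.floor(x)) for x in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in range(cfg.n_core_samples - sum(sizes)):
        sizes[rema[i % len(sizes)]] += 1
    return sizes


def _top_k_indicator(score: np.ndarray, k: int) -> np.ndarray:
    order = np.argsort(-score, kind="stable")
    flag = np.zeros(score.shape[0], dtype=bool)
    flag[order[:k]] = True
    return flag


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate one cohort.  Same config (incl. seed) is bit-identical."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_core_samples
    sample_ids = [f"S{i:03d}" for i in range(n)]
    periphery_ids = [f"S{i:03d}P" for i in range(n)] if cfg.periphery else []

    # --- latent axes: exact bivariate normal at the configured correlation ---
    rho = cfg.axis_correlation
    z = rng.standard_normal((n, 2))
    infl = z[:, 0]
    calc = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    latent_pg = 0.7 * rng.standard_normal(n)
    latent_smc = 0.7 * rng.standard_normal(n)
    latent_struct = 0.7 * rng.standard_normal(n)

    # --- phenotype clusters -------------------------------------------------
    sizes = _phenotype_sizes(cfg)
    cluster = np.repeat(np.arange(cfg.n_phenotypes), sizes)
    cluster = cluster[rng.permutation(n)]

    # --- group labels from propensities (top-k keeps counts exact) ----------
    female = _top_k_indicator(
        2.5 * (cluster == 3) + rng.standard_normal(n),
        cfg.group_counts.get("female", 29))
    calcified = _top_k_indicator(
        calc + 1.5 * (cluster == 3), cfg.group_counts.get("calcified", 60))
    symptomatic = _top_k_indicator(infl, cfg.group_counts.get("symptomatic", 36))
    statin = rng.random(n) < 0.65
    age = np.clip(rng.normal(70.0, 8.0, n), 45.0, 90.0)

    # ultrasound class tracks calcification (echogenic) vs inflammation
    # (echolucent) with noise; a small fraction is unrecorded
    us_score = calc - infl + 0.7 * rng.standard_normal(n)
    terciles = np.quantile(us_score, [1 / 3, 2 / 3])
    ultrasound = np.where(us_score < terciles[0], "echolucent",
                          np.where(us_score < terciles[1], "mixed",
                                   "echogenic")).astype(object)
    ultrasound[rng.random(n) < 0.02] = "unknown"

    latent = pd.DataFrame(
        {"inflammation": infl, "calcification": calc,
         "proteoglycan": latent_pg, "smc": latent_smc,
         "structural_ecm": latent_struct},
        index=sample_ids)
    axis_of = {"inflammation": infl, "calcification": calc,
               "proteoglycan": latent_pg, "smc": latent_smc,
               "structural_ecm": latent_struct}

    # --- protein matrices ---------------------------------------------------
    sep_shift = cfg.phenotype_separation * cfg.noise_sd / 2.0
    matrices: dict[str, AbundanceMatrix] = {}
    signal_store: dict[str, pd.DataFrame] = {}
    blocks: dict[str, dict[str, list[str]]] = {}
    ann_rows: dict[str, tuple[str, set[str]]] = {}

    for fraction in (Fraction.SDS, Fraction.NACL, Fraction.GUHCL):
        fname = fraction.value
        anchors = ANCHORS[fraction]
        marker_axes = MARKER_AXES[fraction]
        protein_ids: list[str] = []
        fraction_blocks: dict[str, list[str]] = {}

        anchors = {tag: list(members) for tag, members in anchors.items()}
        if cfg.extra_axis_members > 0:
            # signatures in tissue proteomes run to dozens of members; the
            # named anchors can be padded with generic co-regulated proteins
            for tag in list(anchors):
                anchors[tag] = anchors[tag] + [
                    f"{fname.upper()}X_{tag[:4].upper()}{j:02d}"
                    for j in range(cfg.extra_axis_members)]
        for tag, members in anchors.items():
            protein_ids.extend(members)
            fraction_blocks.setdefault(tag, []).extend(members)
        marker_ids: dict[str, list[str]] = {}
        for axis in marker_axes:
            ids = [f"{fname.upper()}M_{axis[:4].upper()}{j:02d}"
                   for j in range(cfg.markers_per_axis)]
            marker_ids[axis] = ids
            protein_ids.extend(ids)
            fraction_blocks.setdefault(f"{axis}_markers", []).extend(ids)

        n_named = len(protein_ids)
        n_total = int(cfg.n_proteins.get(fname, n_named))
        n_filler = max(0, n_total - n_named)
        fillers = [f"{fname.upper()}_P{j:04d}" for j in range(n_filler)]
        protein_ids = protein_ids + fillers
        p = len(protein_ids)

        signal = np.zeros((p, n))
        baseline = rng.normal(0.0, 1.0, p)
        row_of = {pid: i for i, pid in enumerate(protein_ids)}

        for tag, members in anchors.items():
            axis_score = axis_of[tag]
            for pid in members:
                signal[row_of[pid]] += cfg.loading * axis_score
        # planted sex effect on the proteoglycan anchors
        for pid in anchors.get("proteoglycan", []):
            signal[row_of[pid]] += cfg.effect_size * female
        # phenotype-cluster shifts on the marker blocks
        for axis, ids in marker_ids.items():
            profile = CENTROIDS[axis].to_numpy()[cluster]
            for pid in ids:
                gain = rng.uniform(0.8, 1.2)
                signal[row_of[pid]] += sep_shift * gain * profile

        values = baseline[:, None] + signal + rng.normal(0.0, cfg.noise_sd,
                                                         (p, n))
        if cfg.periphery:
            # paired periphery sample per patient: same molecular signal,
            # attenuated (the core concentrates the disease processes)
            periph = (baseline[:, None]
                      + cfg.periphery_attenuation * signal
                      + rng.normal(0.0, cfg.noise_sd, (p, n)))
            values = np.hstack([values, periph])

        # missingness
        if cfg.missing_rate > 0:
            if cfg.intensity_dependent_missing:
                # lower-abundance cells are more likely to be missing
                flat = values.ravel().argsort().argsort().reshape(values.shape)
                prob = cfg.missing_rate * 2 * (1 - flat / values.size)
            else:
                prob = np.full(values.shape, cfg.missing_rate)
            mask = rng.random(values.shape) < prob
            values = np.where(mask, np.nan, values)

        data = pd.DataFrame(values, index=protein_ids,
                            columns=sample_ids + periphery_ids)
        matrices[fname] = AbundanceMatrix(fraction, data)
        signal_store[fname] = pd.DataFrame(
            baseline[:, None] + signal, index=protein_ids, columns=sample_ids)
        blocks[fname] = fraction_blocks

        # annotation: matrisome fractions are matrisome by construction
        for pid in protein_ids:
            tags = {t for t, mem in fraction_blocks.items()
                    if pid in mem and not t.endswith("_markers")}
            tags |= {t[:-len("_markers")] for t, mem in fraction_blocks.items()
                     if pid in mem and t.endswith("_markers")}
            if fraction is Fraction.GUHCL:
                mclass = "core_matrisome"
            elif fraction is Fraction.NACL:
                mclass = "matrisome_associated"
            else:
                mclass = ("matrisome_associated"
                          if tags & {"inflammation", "calcification"}
                          else "non_matrisome")
            prev_class, prev_tags = ann_rows.get(pid, (None, set()))
            if prev_class is not None:
                mclass = prev_class  # first fraction seen fixes the class
            ann_rows[pid] = (mclass, prev_tags | tags)

    # --- survival: exponential hazards from the prognostic quartet ----------
    quartet = {"CNN1": ("SDS", "CNN1"), "PROC": ("GuHCl", "PROC"),
               "SERPH": ("GuHCl", "SERPH"), "CSPG2": ("GuHCl", "CSPG2")}
    lp = np.zeros(n)
    for pid, coef in cfg.hazard_coefs.items():
        frac, row = quartet.get(pid, ("GuHCl", pid))
        if row in signal_store[frac].index:
            x = signal_store[frac].loc[row].to_numpy()
            sd = x.std()
            zrow = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
            lp += coef * zrow
    rate = cfg.hazard_baseline * np.exp(lp)
    t_event = rng.exponential(1.0 / np.clip(rate, 1e-12, None))
    t_drop = (rng.exponential(1.0 / cfg.dropout_rate, n)
              if cfg.dropout_rate > 0 else np.full(n, np.inf))
    follow_up = np.minimum(np.minimum(t_event, t_drop), cfg.followup_horizon)
    event = t_event <= np.minimum(t_drop, cfg.followup_horizon)

    # estradiol: measured in females, anti-correlated with proteoglycan score
    estradiol = np.full(n, np.nan)
    estradiol[female] = (100.0 + 25.0 * (cfg.estradiol_slope * latent_pg[female]
                                         + np.sqrt(max(0.0, 1 - cfg.estradiol_slope**2))
                                         * rng.standard_normal(int(female.sum()))))

    rep = 2 if cfg.periphery else 1  # periphery rows duplicate the patient
    meta = pd.DataFrame({
        "sample_id": sample_ids + periphery_ids,
        "patient_id": [f"P{i:03d}" for i in range(n)] * rep,
        "region": ["core"] * n + ["periphery"] * (n * (rep - 1)),
        "sex": np.tile(np.where(female, "female", "male"), rep),
        "calcified": np.tile(calcified, rep),
        "symptomatic": np.tile(symptomatic, rep),
        "statin": np.tile(statin, rep),
        "age": np.tile(age, rep),
        "ultrasound": np.tile(ultrasound, rep),
        "follow_up": np.tile(follow_up, rep),
        "event": np.tile(event, rep),
        "estradiol": np.tile(estradiol, rep),
    })
    metadata = SampleMetadata(meta)

    # --- realized noise-free log2FC truth per contrast ----------------------
    contrasts = {"calcified": calcified, "symptomatic": symptomatic,
                 "female": female}
    log2fc: dict[str, pd.DataFrame] = {}
    for fname, sig in signal_store.items():
        cols = {}
        for cname, flag in contrasts.items():
            cols[cname] = (sig.loc[:, np.asarray(flag)].mean(axis=1)
                           - sig.loc[:, ~np.asarray(flag)].mean(axis=1))
        log2fc[fname] = pd.DataFrame(cols)

    ann_table = pd.DataFrame({
        "protein_id": list(ann_rows),
        "matrisome_class": [c for c, _ in ann_rows.values()],
        "signature_tags": [";".join(sorted(t)) for _, t in ann_rows.values()],
    })
    annotation = AnnotationTable(ann_table)

    truth = StudyTruth(
        latent=latent,
        log2fc=log2fc,
        phenotype=pd.Series(cluster, index=sample_ids, name="phenotype"),
        hazard_lp=pd.Series(lp, index=sample_ids, name="hazard_lp"),
        blocks=blocks,
    )
    return SimulatedStudy(matrices=matrices, metadata=metadata,
                          annotation=annotation, truth=truth, config=cfg)


def simulate_risk_panel(
    seed: int,
    n_samples: int = 200,
    n_features: int = 40,
    n_informative: int = 4,
    beta: float = 0.8,
    baseline_rate_horizon: float = 0.35,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Latent-risk candidate panel for outcome-signature selection.

    ``n_informative`` planted proteins (named after the prognostic quartet
    when four) carry log-hazard ``beta`` each; the remainder are null.  The
    binary outcome is an event within a fixed horizon under an exponential
    hazard.  Returns (features, outcome, planted feature names).
    """
    rng = np.random.default_rng(seed)
    planted = ["CNN1", "PROC", "SERPH", "CSPG2"][:n_informative]
    planted += [f"INF{i}" for i in range(max(0, n_informative - 4))]
    nulls = [f"NULL{i:02d}" for i in range(n_features - n_informative)]
    names = planted + nulls
    x = rng.standard_normal((n_samples, n_features))
    signs = np.array([1.0, -1.0] * (n_informative // 2 + 1))[:n_informative]
    lp = x[:, :n_informative] @ (beta * signs)
    t = rng.exponential(1.0 / (np.exp(lp)))
    y = (t * baseline_rate_horizon ** -1 < 1.0).astype(int)  # T < 1/rate0
    features = pd.DataFrame(x, columns=names,
                            index=[f"S{i:03d}" for i in range(n_samples)])
    return features, y, planted


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Write the three matrices, metadata, annotation and truth JSON as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fname, m in study.matrices.items():
        write_abundance_table(m, out / f"abundance_{fname}.tsv")
    write_sample_metadata(study.metadata, out / "metadata.tsv")
    write_annotation_table(study.annotation, out / "annotation.tsv")
    truth = {
        "latent": study.truth.latent.round(6).to_dict(orient="index"),
        "phenotype": study.truth.phenotype.to_dict(),
        "hazard_lp": study.truth.hazard_lp.round(6).to_dict(),
        "log2fc": {f: df.round(6).to_dict(orient="index")
                   for f, df in study.truth.log2fc.items()},
        "blocks": study.truth.blocks,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
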