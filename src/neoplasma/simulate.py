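"""Synthetic paired-design cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes: every participant
contributes a birth sample (DOL0) plus exactly one follow-up sample at DOL
1, 3 or 7; log2 protein intensities follow a random-intercept model with
per-protein day-of-life trajectory classes, batch location/scale effects
and intensity-dependent left-censored (MNAR) missingness; immunoglobulin
iBAQ values follow first-order kinetics, C(t) = C(0) * 2^(-t / t_half) for
maternally transferred decaying species and doubling-time growth for IgM
and J chain (with a shared participant-level growth latent coupling the
two); whole-blood RNA counts are negative-binomial around means engineered
to a target protein-mRNA concordance at the change-vs-DOL0 level.

Defaults are chosen to resemble a small newborn plasma LFQ cohort: 30
participants split 10/10/10 over follow-up days, ~200 plasma proteins,
subject SD 0.5 and residual SD 0.3 log2 units, ~15% abundance-driven
missingness, an IgG1 half-life of 21.1 days inside the literature range
for in vivo IgG1 decay, and an elevated newborn IgG1:IgG2 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import FOLLOWUP_DOLS, ProteinQuantMatrix, RnaCountMatrix, validate_sample_meta

TRAJECTORY_CLASSES = ("flat", "increasing", "decreasing", "acute_dol1")


class ConfigError(ValueError):
    pass


@dataclass
class IgSpec:
    """Kinetics of one immunoglobulin species.

    Exactly one of ``half_life_days`` (first-order decay) or
    ``doubling_days`` (growth) is set; ``synthesis_rate`` adds a linear
    log2-per-day synthesis term on top of decay.
    """

    baseline_ibaq: float
    half_life_days: float | None = None
    doubling_days: float | None = None
    synthesis_rate: float = 0.0

    @property
    def rate(self) -> float:
        """Net log2 change per day."""
        r = 0.0
        if self.half_life_days is not None:
            if self.half_life_days <= 0:
                raise ConfigError("half_life_days must be positive")
            r -= 1.0 / self.half_life_days
        if self.doubling_days is not None:
            if self.doubling_days <= 0:
                raise ConfigError("doubling_days must be positive")
            r += 1.0 / self.doubling_days
        return r + self.synthesis_rate


def default_ig_panel() -> dict[str, IgSpec]:
    # newborn subclass ordering IgG1 > IgG2 > IgG3 > IgG4 with the elevated
    # IgG1:IgG2 ratio characteristic of preferential placental transfer;
    # IgG3 clears faster than the other subclasses
    return {
        "IGHG1": IgSpec(baseline_ibaq=4.0e9, half_life_days=21.1),
        "IGHG2": IgSpec(baseline_ibaq=1.0e9, half_life_days=21.0),
        "IGHG3": IgSpec(baseline_ibaq=3.0e8, half_life_days=7.0),
        "IGHG4": IgSpec(baseline_ibaq=1.5e8, half_life_days=21.0),
        "IGHM": IgSpec(baseline_ibaq=5.0e8, doubling_days=5.5),
        "JCHAIN": IgSpec(baseline_ibaq=2.0e8, doubling_days=5.5),
    }


def default_trajectory_classes() -> dict[str, float]:
    return {"flat": 0.55, "increasing": 0.20, "decreasing": 0.15, "acute_dol1": 0.10}


def default_batch_effects() -> dict[str, tuple[float, float]]:
    return {"plateA": (0.0, 1.0), "plateB": (0.5, 1.2)}


@dataclass
class SimConfig:
    n_participants: int = 30
    followup_split: tuple[int, int, int] = (10, 10, 10)
    n_proteins: int = 200
    trajectory_classes: dict[str, float] = field(default_factory=default_trajectory_classes)
    effect_range: tuple[float, float] = (0.2, 1.5)
    baseline_mean: float = 26.0
    baseline_sd: float = 2.0
    subject_sd: float = 0.5
    residual_sd: float = 0.3
    sex_effect: float = 0.0
    batch_effects: dict[str, tuple[float, float]] = field(default_factory=default_batch_effects)
    censor_quantile: float = 0.15      # 0 disables censoring
    censor_steepness: float = 2.0      # per log2 unit
    ig_panel: dict[str, IgSpec] = field(default_factory=default_ig_panel)
    ig_growth_sd: float = 0.4          # participant-level spread of growth rates
    igm_jchain_coupling: float = 0.75  # shared fraction of that spread
    n_genes: int = 30
    n_concordant: int = 7
    r_high: float = 0.85
    r_low: float = 0.10
    rna_concordance: dict[str, float] | None = None  # per-gene overrides
    rna_lfc_scale: float = 0.5
    rna_base_count: float = 2000.0
    rna_dispersion: float = 0.05
    cohort: str = "main"
    seed: int = 0

    def validate(self) -> None:
        if sum(self.followup_split) != self.n_participants:
            raise ConfigError("followup_split must sum to n_participants")
        frac = sum(self.trajectory_classes.values())
        if abs(frac - 1.0) > 1e-9:
            raise ConfigError("trajectory class fractions must sum to 1")
        unknown = set(self.trajectory_classes) - set(TRAJECTORY_CLASSES)
        if unknown:
            raise ConfigError(f"unknown trajectory classes: {sorted(unknown)}")
        if self.residual_sd < 0 or self.subject_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        for spec in self.ig_panel.values():
            spec.rate  # validates positivity
        targets = list((self.rna_concordance or {}).values()) + [self.r_high, self.r_low]
        if any(abs(r) > 1 for r in targets):
            raise ConfigError("concordance targets must satisfy |R| <= 1")
        if not 0 <= self.censor_quantile < 1:
            raise ConfigError("censor_quantile must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cohort."""

    protein_effects: pd.DataFrame   # protein, gene, class, lfc_dol1/3/7
    batch_effects: pd.DataFrame     # batch, location, scale
    ig_truth: pd.DataFrame          # gene, baseline_ibaq, rate, half_life_days
    rna_truth: pd.DataFrame         # gene, protein, target_r
    censor_threshold: float | None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("protein_effects", "batch_effects", "ig_truth", "rna_truth"):
            getattr(self, name).to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


_CLASS_PROFILE = {
    # relative trajectory shape at DOL 1, 3, 7 (multiplied by the effect size)
    "flat": np.array([0.0, 0.0, 0.0]),
    "increasing": np.array([np.log2(2) / 3, np.log2(4) / 3, 1.0]),
    "decreasing": -np.array([np.log2(2) / 3, np.log2(4) / 3, 1.0]),
    "acute_dol1": np.array([1.0, 0.0, 0.0]),
}


def _make_meta(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    batches = list(cfg.batch_effects) or ["batch0"]
    pid = 0
    for day, count in zip(FOLLOWUP_DOLS, cfg.followup_split):
        for _ in range(count):
            pid += 1
            participant = f"P{pid:03d}"
            sex = "M" if rng.random() < 0.5 else "F"
            batch = batches[(pid - 1) % len(batches)]
            for dol in (0, day):
                rows.append(
                    {
                        "sample_id": f"{participant}_D{dol}",
                        "participant_id": participant,
                        "dol": dol,
                        "sex": sex,
                        "batch": batch,
                        "cohort": cfg.cohort,
                    }
                )
    return validate_sample_meta(pd.DataFrame(rows))


def generate_cohort(
    config: SimConfig,
) -> tuple[ProteinQuantMatrix, RnaCountMatrix, pd.DataFrame, SimTruth]:
    """Generate one cohort; all randomness flows from ``config.seed``."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    meta = _make_meta(cfg, rng)
    samples = meta["sample_id"].tolist()
    n_samples = len(samples)
    dol = meta["dol"].to_numpy()
    participants = meta["participant_id"].to_numpy()
    uniq_pids, pid_codes = np.unique(participants, return_inverse=True)
    n_pid = len(uniq_pids)
    sex_m = (meta["sex"] == "M").to_numpy(float)
    batches = list(cfg.batch_effects) or ["batch0"]
    batch_codes = meta["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    batch_loc = np.array([cfg.batch_effects.get(b, (0.0, 1.0))[0] for b in batches])
    batch_scale = np.array([cfg.batch_effects.get(b, (0.0, 1.0))[1] for b in batches])

    # ---- bulk proteome -------------------------------------------------
    P = cfg.n_proteins
    class_names = list(cfg.trajectory_classes)
    class_fracs = np.array([cfg.trajectory_classes[c] for c in class_names])
    counts = np.floor(class_fracs * P).astype(int)
    counts[0] += P - counts.sum()
    classes = np.repeat(class_names, counts)
    rng.shuffle(classes)
    magnitude = rng.uniform(*cfg.effect_range, size=P)
    profiles = np.stack([_CLASS_PROFILE[c] for c in classes])  # (P, 3)
    true_lfc = profiles * magnitude[:, None]                   # at DOL 1, 3, 7
    day_index = {1: 0, 3: 1, 7: 2}
    effect = np.zeros((P, n_samples))
    for j, d in enumerate(dol):
        if d != 0:
            effect[:, j] = true_lfc[:, day_index[d]]

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=P)
    subject = rng.normal(0.0, cfg.subject_sd, size=(P, n_pid))
    noise = rng.normal(0.0, cfg.residual_sd, size=(P, n_samples))
    Y = (
        baseline[:, None]
        + subject[:, pid_codes]
        + effect
        + cfg.sex_effect * sex_m[None, :]
        + batch_loc[batch_codes][None, :]
        + batch_scale[batch_codes][None, :] * noise
    )

    protein_ids = [f"PROT{i + 1:04d}" for i in range(P)]
    gene_names = [f"GENE{i + 1:04d}" for i in range(P)]

    # ---- immunoglobulin panel -----------------------------------------
    ig_genes = list(cfg.ig_panel)
    n_ig = len(ig_genes)
    a_part = rng.normal(0.0, cfg.subject_sd, size=n_pid)  # shared per-sample loading
    lam_shared = rng.normal(0.0, 1.0, size=n_pid)
    ig_rows = np.zeros((n_ig, n_samples))
    ig_ibaq = np.zeros((n_ig, n_samples))
    ig_truth_rows = []
    c = cfg.igm_jchain_coupling
    for k, gene in enumerate(ig_genes):
        spec = cfg.ig_panel[gene]
        rate = spec.rate
        if spec.doubling_days is not None:
            lam_own = rng.normal(0.0, 1.0, size=n_pid)
            mult = 1.0 + cfg.ig_growth_sd * (
                np.sqrt(c) * lam_shared + np.sqrt(1.0 - c) * lam_own
            )
        else:
            mult = np.ones(n_pid)
        eps = rng.normal(0.0, cfg.residual_sd, size=n_samples)
        dev = a_part[pid_codes] + rate * dol * mult[pid_codes] + eps
        ig_rows[k] = np.log2(spec.baseline_ibaq) + 10.0 + dev  # keep Ig high-abundance
        ig_ibaq[k] = spec.baseline_ibaq * 2.0**dev
        ig_truth_rows.append(
            {
                "gene": gene,
                "baseline_ibaq": spec.baseline_ibaq,
                "rate_log2_per_day": rate,
                "half_life_days": (-1.0 / rate) if rate < 0 else np.inf,
                "kind": "decay" if spec.half_life_days is not None else "growth",
            }
        )

    all_ids = protein_ids + [f"IG_{g}" for g in ig_genes]
    all_genes = gene_names + ig_genes
    Y_all = np.vstack([Y, ig_rows])

    # ---- MNAR censoring ------------------------------------------------
    censor_threshold = None
    lfq = Y_all.copy()
    if cfg.censor_quantile > 0:
        censor_threshold = float(np.quantile(Y_all, cfg.censor_quantile))
        p_miss = expit(cfg.censor_steepness * (censor_threshold - Y_all))
        lfq = np.where(rng.random(Y_all.shape) < p_miss, np.nan, Y_all)

    if n_ig:
        ibaq = np.full_like(Y_all, np.nan)
        ibaq[P:, :] = ig_ibaq
        ibaq[P:, :][np.isnan(lfq[P:, :])] = np.nan
    else:
        ibaq = None

    records = pd.DataFrame(
        {
            "protein_group_id": all_ids,
            "gene_name": all_genes,
            "is_reverse": False,
            "is_contaminant": False,
            "only_modified_site": False,
            "unique_peptides": rng.integers(2, 30, size=len(all_ids)),
        },
        index=pd.Index(all_ids, name="protein_group_id"),
    )
    matrix = ProteinQuantMatrix(
        records=records,
        lfq=pd.DataFrame(lfq, index=records.index, columns=samples),
        ibaq=None if ibaq is None
        else pd.DataFrame(ibaq, index=records.index, columns=samples),
    )

    # ---- RNA counts engineered to target concordance -------------------
    n_genes = min(cfg.n_genes, P)
    targets = np.full(n_genes, cfg.r_low)
    targets[: min(cfg.n_concordant, n_genes)] = cfg.r_high
    gene_subset = gene_names[:n_genes]
    if cfg.rna_concordance:
        for i, g in enumerate(gene_subset):
            if g in cfg.rna_concordance:
                targets[i] = cfg.rna_concordance[g]
    if np.any(np.abs(targets) > 1):
        raise ConfigError("concordance targets must satisfy |R| <= 1")

    is_follow = dol != 0
    base_col = {p: f"{p}_D0" for p in uniq_pids}
    col_of = {s: j for j, s in enumerate(samples)}
    follow_idx = np.where(is_follow)[0]
    base_idx = np.array([col_of[base_col[participants[j]]] for j in follow_idx])

    size_factor = 2.0 ** rng.normal(0.0, 0.1, size=n_samples)
    base_counts = cfg.rna_base_count * 2.0 ** rng.normal(0.0, 1.0, size=n_genes)
    mu = base_counts[:, None] * size_factor[None, :] * np.ones((n_genes, n_samples))
    for gi in range(n_genes):
        prot_delta = Y[gi, follow_idx] - Y[gi, base_idx]
        sd = prot_delta.std()
        z = (prot_delta - prot_delta.mean()) / (sd if sd > 0 else 1.0)
        r = targets[gi]
        latent = cfg.rna_lfc_scale * (
            r * z + np.sqrt(max(0.0, 1.0 - r**2)) * rng.normal(size=len(follow_idx))
        )
        mu[gi, follow_idx] *= 2.0**latent
    nb_n = 1.0 / cfg.rna_dispersion
    counts_mat = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
    rna = RnaCountMatrix(
        counts=pd.DataFrame(counts_mat.astype(np.int64),
                            index=pd.Index(gene_subset, name="gene_id"),
                            columns=samples)
    )

    truth = SimTruth(
        protein_effects=pd.DataFrame(
            {
                "protein": all_ids,
                "gene": all_genes,
                "class": list(classes) + ["ig_" + r["kind"] for r in ig_truth_rows],
                "lfc_dol1": np.concatenate(
                    [true_lfc[:, 0], [r["rate_log2_per_day"] * 1 for r in ig_truth_rows]]
                ),
                "lfc_dol3": np.concatenate(
                    [true_lfc[:, 1], [r["rate_log2_per_day"] * 3 for r in ig_truth_rows]]
                ),
                "lfc_dol7": np.concatenate(
                    [true_lfc[:, 2], [r["rate_log2_per_day"] * 7 for r in ig_truth_rows]]
                ),
            }
        ),
        batch_effects=pd.DataFrame(
            {
                "batch": batches,
                "location": batch_loc,
                "scale": batch_scale,
            }
        ),
        ig_truth=pd.DataFrame(ig_truth_rows),
        rna_truth=pd.DataFrame(
            {"gene": gene_subset, "protein": protein_ids[:n_genes], "target_r": targets}
        ),
        censor_threshold=censor_threshold,
    )
    return matrix, rna, meta, truth


def inject_flag_rows(
    matrix: ProteinQuantMatrix,
    n_contaminants: int,
    n_reverse: int,
    seed: int = 0,
) -> tuple[ProteinQuantMatrix, pd.DataFrame]:
    """Append contaminant / decoy rows with plausible intensities.

    Returns the augmented matrix and a bookkeeping frame of the injected
    row IDs and their flags, so downstream filtering can be audited.
    """
    rng = np.random.default_rng(seed)
    lfq = matrix.lfq.to_numpy(float)
    mu = float(np.nanmean(lfq))
    sd = float(np.nanstd(lfq))
    rows, new_records, book = [], [], []
    for i in range(n_contaminants + n_reverse):
        kind = "CON" if i < n_contaminants else "REV"
        rid = f"{kind}__{i + 1:03d}"
        rows.append(rng.normal(mu, sd, size=len(matrix.samples)))
        new_records.append(
            {
                "protein_group_id": rid,
                "gene_name": "",
                "is_reverse": kind == "REV",
                "is_contaminant": kind == "CON",
                "only_modified_site": False,
                "unique_peptides": int(rng.integers(1, 5)),
            }
        )
        book.append({"protein_group_id": rid,
                     "is_contaminant": kind == "CON", "is_reverse": kind == "REV"})
    if not rows:
        return matrix.copy(), pd.DataFrame(
            columns=["protein_group_id", "is_contaminant", "is_reverse"]
        )
    add_rec = pd.DataFrame(new_records)
    add_rec.index = pd.Index(add_rec["protein_group_id"], name="protein_group_id")
    add_lfq = pd.DataFrame(np.vstack(rows), index=add_rec.index, columns=matrix.samples)
    records = pd.concat([matrix.records, add_rec])
    lfq_df = pd.concat([matrix.lfq, add_lfq])
    ibaq = None
    if matrix.ibaq is not None:
        add_ibaq = pd.DataFrame(np.nan, index=add_rec.index, columns=matrix.samples)
        ibaq = pd.concat([matrix.ibaq, add_ibaq])
    out = ProteinQuantMatrix(records=records, lfq=lfq_df, ibaq=ibaq,
                             imputed=matrix.imputed)
    return out, pd.DataFrame(book)


def write_maxquant_like(matrix: ProteinQuantMatrix, meta: pd.DataFrame,
                        path: str | Path) -> None:
    """Emit the proteinGroups TSV dialect read by ``read_protein_groups``:
    LFQ de-logged with missing encoded as 0, flags as "+"/empty."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec = matrix.records
    cols: dict[str, np.ndarray] = {
        "Protein IDs": rec["protein_group_id"].to_numpy(),
        "Gene names": rec["gene_name"].to_numpy(),
        "Reverse": np.where(rec["is_reverse"], "+", ""),
        "Potential contaminant": np.where(rec["is_contaminant"], "+", ""),
        "Only identified by site": np.where(rec["only_modified_site"], "+", ""),
        "Razor + unique peptides": rec["unique_peptides"].to_numpy(),
    }
    for s in matrix.samples:
        vals = 2.0 ** matrix.lfq[s].to_numpy(float)
        cols[f"LFQ intensity {s}"] = np.where(np.isnan(vals), 0.0, vals)
    if matrix.ibaq is not None:
        for s in matrix.samples:
            vals = matrix.ibaq[s].to_numpy(float)
            cols[f"iBAQ {s}"] = np.where(np.isnan(vals), 0.0, vals)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def save_cohort(matrix: ProteinQuantMatrix, rna: RnaCountMatrix, meta: pd.DataFrame,
                truth: SimTruth, outdir: str | Path) -> None:
    """Write a full cohort in the interchange dialects plus the truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_maxquant_like(matrix, meta, outdir / "proteinGroups.txt")
    meta.to_csv(outdir / "sample_meta.csv", index=False)
    rna.counts.to_csv(outdir / "rna_counts.tsv", sep="\t")
    truth.write(outdir)
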