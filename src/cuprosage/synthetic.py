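"""Synthetic cohort and drug-world generators.

Every input the pipeline consumes can be generated here with the statistical
structure the downstream analysis assumes: tumour/normal expression with a
differentially expressed cuproptosis-like panel, survival times driven by a
known (partly nonlinear) function of a gene subset, censoring, clinical
covariates linked to true risk, a cell-line expression → IC50 panel, per-sample
mutation counts, and a bipartite drug–target world with latent-factor
interaction structure, entity connection networks and a target similarity
matrix.

All randomness flows through a single ``numpy.random.Generator`` per call,
seeded from the spec, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CUPROPTOSIS_PANEL = [
    "FDX1", "LIPT1", "LIAS", "DLD", "DBT", "DLST",
    "DLAT", "PDHA1", "PDHB", "SLC31A1", "ATP7A", "ATP7B",
]


class SpecValidationError(ValueError):
    """Raised when a generator spec violates its invariants."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic tumour cohort.

    The defaults emulate the study conditions: a 12-gene cuproptosis-like
    panel of which 10 are differentially expressed tumour vs normal, three
    panel genes drive survival risk linearly with one multiplicative
    interaction on top, exponential event times under a constant baseline
    hazard, independent exponential censoring (~30% of samples censored),
    and clinical covariates whose odds of advanced stage/grade increase with
    true risk so that independence analyses are non-degenerate.
    """

    n_tumor: int = 500
    n_normal: int = 72
    n_genes: int = 2000
    panel_genes: list[str] = field(default_factory=lambda: list(CUPROPTOSIS_PANEL))
    n_de_panel: int = 10              # panel genes actually shifted tumour vs normal
    n_signal_genes: int = 3           # panel genes driving risk (subset of the DE ones)
    effect_sizes: tuple[float, ...] = (1.0, -1.0, 0.8)
    nonlinear_terms: tuple[tuple[int, int, float], ...] = ((0, 2, 0.8),)
    baseline_hazard: float = 0.12     # events per year
    censor_rate: float = 0.035        # censorings per year (~30% censored)
    de_shift: float = 1.0             # log2-scale tumour-vs-normal shift on DE panel genes
    background_de_fraction: float = 0.10
    background_de_shift: float = 1.6
    clinical_link: float = 0.8        # logit slope of stage/grade/T/M on true risk
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_tumor, self.n_normal, self.n_genes) <= 0:
            raise SpecValidationError("all counts must be > 0")
        if self.n_signal_genes > len(self.panel_genes):
            raise SpecValidationError("n_signal_genes exceeds panel size")
        if self.n_de_panel > len(self.panel_genes):
            raise SpecValidationError("n_de_panel exceeds panel size")
        if len(self.effect_sizes) != self.n_signal_genes:
            raise SpecValidationError("effect_sizes length must equal n_signal_genes")
        if self.baseline_hazard <= 0:
            raise SpecValidationError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise SpecValidationError("censor_rate must be >= 0")
        for i, j, _ in self.nonlinear_terms:
            if not (0 <= i < self.n_signal_genes and 0 <= j < self.n_signal_genes):
                raise SpecValidationError("nonlinear term indexes a non-signal gene")


@dataclass
class Cohort:
    """A generated cohort: expression, labels, survival and clinical table."""

    expression: pd.DataFrame        # genes x samples, non-negative
    sample_labels: pd.Series        # 'tumor' / 'normal' per sample
    clinical: pd.DataFrame          # tumour samples: time, event, age, gender, stage, grade, T, M
    true_risk: pd.Series            # generating log-hazard eta per tumour sample
    spec: CohortSpec

    @property
    def tumor_samples(self) -> pd.Index:
        return self.sample_labels.index[self.sample_labels == "tumor"]

    @property
    def normal_samples(self) -> pd.Index:
        return self.sample_labels.index[self.sample_labels == "normal"]


def _signal_matrix(log_expr: pd.DataFrame, spec: CohortSpec, samples) -> np.ndarray:
    """Standardised log-expression of the signal genes, samples x genes."""
    sig_genes = spec.panel_genes[: spec.n_signal_genes]
    Z = log_expr.loc[sig_genes, samples].to_numpy().T
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) == 0, 1.0, Z.std(axis=0))
    return Z


def true_log_hazard(Z: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """eta = sum_i beta_i z_i + sum (i,j,g) g * z_i * z_j on standardised signal genes."""
    eta = Z @ np.asarray(spec.effect_sizes, dtype=float)
    for i, j, g in spec.nonlinear_terms:
        eta = eta + g * Z[:, i] * Z[:, j]
    return eta


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate expression + survival + clinical data under ``spec``.

    Expression is log-normal on the log2 scale; the first ``n_de_panel`` panel
    genes are shifted by ``de_shift`` in tumours with alternating sign.  Event
    times are exponential with per-sample hazard h0 * exp(eta); censoring
    times are exponential with rate ``censor_rate``; the observed time is the
    minimum with an event flag.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    tumor_ids = [f"TUMOR_{i:04d}" for i in range(spec.n_tumor)]
    normal_ids = [f"NORMAL_{i:04d}" for i in range(spec.n_normal)]
    samples = tumor_ids + normal_ids
    n_bg = spec.n_genes - len(spec.panel_genes)
    genes = list(spec.panel_genes) + [f"GENE_{i:05d}" for i in range(n_bg)]

    base = rng.normal(5.0, 1.0, size=spec.n_genes)          # per-gene baseline log2 level
    log_expr = base[:, None] + rng.normal(0.0, 1.0, size=(spec.n_genes, len(samples)))

    # differential shift on panel genes (tumour columns only), alternating direction
    tum = np.arange(spec.n_tumor)
    for k in range(spec.n_de_panel):
        direction = 1.0 if k % 2 == 0 else -1.0
        log_expr[k, tum] += direction * spec.de_shift
    # background DEGs so genome-wide screens have structure
    if spec.background_de_fraction > 0 and n_bg > 0:
        n_de_bg = int(round(spec.background_de_fraction * n_bg))
        de_idx = len(spec.panel_genes) + rng.choice(n_bg, size=n_de_bg, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de_bg)
        log_expr[de_idx[:, None], tum[None, :]] += (signs * spec.background_de_shift)[:, None]

    expression = pd.DataFrame(2.0 ** log_expr, index=genes, columns=samples)
    log_df = pd.DataFrame(log_expr, index=genes, columns=samples)
    labels = pd.Series(["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal,
                       index=samples, name="label")

    Z = _signal_matrix(log_df, spec, tumor_ids)
    eta = true_log_hazard(Z, spec)
    hazard = spec.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censor_rate, size=spec.n_tumor)
    else:
        censor_time = np.full(spec.n_tumor, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    # clinical covariates: ordinal stage/grade/T via logistic links to eta, binary M
    def ordinal(levels: int, slope: float) -> np.ndarray:
        # cumulative-logit draw: higher eta -> higher level odds
        cuts = np.linspace(-1.0, 1.0, levels - 1)
        u = slope * eta + rng.logistic(0.0, 1.0, size=spec.n_tumor)
        return 1 + (u[:, None] > cuts[None, :]).sum(axis=1)

    clinical = pd.DataFrame({
        "time": np.maximum(time, 1e-4),
        "event": event,
        "age": np.round(rng.normal(60.0, 10.0, size=spec.n_tumor)).clip(25, 90),
        "gender": rng.binomial(1, 0.65, size=spec.n_tumor),    # no link: non-prognostic
        "stage": ordinal(4, spec.clinical_link),
        "grade": ordinal(4, spec.clinical_link),
        "T": ordinal(4, spec.clinical_link),
        "M": rng.binomial(1, 1.0 / (1.0 + np.exp(-(spec.clinical_link * eta - 1.5)))),
    }, index=pd.Index(tumor_ids, name="sample_id"))

    return Cohort(expression=expression, sample_labels=labels, clinical=clinical,
                  true_risk=pd.Series(eta, index=tumor_ids, name="true_risk"), spec=spec)


# ---------------------------------------------------------------------------
# drug-target world
# ---------------------------------------------------------------------------

@dataclass
class DrugWorldSpec:
    """Parameters of the synthetic drug-target interaction world.

    Interactions are planted through latent factors: each drug and target
    carries a ``latent_dim``-dimensional factor and the top
    ``interaction_density`` fraction of latent inner products become label-1
    pairs.  Raw feature vectors embed the latent factors in a recorded subset
    of columns (so feature selection is recoverable); connection networks are
    Bernoulli with enrichment between entities sharing interaction partners;
    target similarity is latent cosine similarity plus noise clipped to [0,1].
    """

    n_drugs: int = 15
    n_targets: int = 100
    # asymmetric on purpose: drugs carry short descriptor vectors, targets
    # long protein feature vectors (sums to 9975 pre-selection)
    n_drug_features: int = 975
    n_target_features: int = 9000
    interaction_density: float = 0.25
    latent_dim: int = 5
    connection_density_drugs: float = 0.30
    connection_density_targets: float = 0.30
    shared_partner_boost: float = 0.35
    latent_mean: float = 0.7          # shared mean direction of the factors
    similarity_noise: float = 0.05
    latent_feature_scale: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_drugs, self.n_targets,
               self.n_drug_features, self.n_target_features) <= 0:
            raise SpecValidationError("all counts must be > 0")
        for d in (self.interaction_density, self.connection_density_drugs,
                  self.connection_density_targets):
            if not (0.0 < d <= 1.0):
                raise SpecValidationError("densities must be in (0, 1]")
        if self.latent_dim < 1:
            raise SpecValidationError("latent_dim must be >= 1")
        if self.similarity_noise < 0:
            raise SpecValidationError("similarity_noise must be >= 0")


@dataclass
class DrugWorld:
    drugs: pd.DataFrame                 # id, name
    targets: pd.DataFrame               # id, name
    interactions: pd.DataFrame          # drug, target (label-1 pairs)
    drug_connections: pd.DataFrame      # symmetric boolean matrix, drug x drug
    target_connections: pd.DataFrame    # symmetric boolean matrix, target x target
    target_similarity: pd.DataFrame     # target x target in [0,1]
    drug_features: pd.DataFrame         # drug x feature
    target_features: pd.DataFrame       # target x feature
    latent_drug: np.ndarray
    latent_target: np.ndarray
    metadata: dict

    def interaction_set(self) -> set[tuple[str, str]]:
        return set(zip(self.interactions["drug"], self.interactions["target"]))


def _symmetric_bernoulli(rng, n: int, p: np.ndarray) -> np.ndarray:
    u = rng.random((n, n))
    u = np.triu(u, 1)
    mat = (u < np.triu(p, 1))
    mat = mat | mat.T
    np.fill_diagonal(mat, False)
    return mat


def generate_drug_world(spec: DrugWorldSpec) -> DrugWorld:
    """Generate the drug-target world under ``spec`` (see class docstring)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    drug_ids = [f"DRUG_{i:03d}" for i in range(spec.n_drugs)]
    target_ids = [f"TGT_{i:03d}" for i in range(spec.n_targets)]

    # factors share a mean direction so the inner product has a linear
    # marginal component per coordinate (univariate selection can recover
    # the informative feature columns)
    U = (spec.latent_mean + rng.normal(size=(spec.n_drugs, spec.latent_dim))
         ) / np.sqrt(spec.latent_dim)
    V = (spec.latent_mean + rng.normal(size=(spec.n_targets, spec.latent_dim))
         ) / np.sqrt(spec.latent_dim)

    scores = U @ V.T
    n_pos = int(round(spec.interaction_density * scores.size))
    flat = scores.ravel()
    # top-n_pos pairs by latent agreement; ties broken by index (deterministic)
    order = np.argsort(-flat, kind="stable")
    labels = np.zeros(scores.size, dtype=bool)
    labels[order[:n_pos]] = True
    labels = labels.reshape(scores.shape)

    inter = pd.DataFrame(
        [(drug_ids[i], target_ids[j]) for i, j in zip(*np.nonzero(labels))],
        columns=["drug", "target"],
    )

    def shared_partner(mat: np.ndarray) -> np.ndarray:
        shared = (mat.astype(int) @ mat.T.astype(int)) > 0
        return shared

    p_d = np.full((spec.n_drugs, spec.n_drugs), spec.connection_density_drugs)
    p_d[shared_partner(labels)] = min(
        1.0, spec.connection_density_drugs + spec.shared_partner_boost)
    dconn = _symmetric_bernoulli(rng, spec.n_drugs, p_d)

    p_t = np.full((spec.n_targets, spec.n_targets), spec.connection_density_targets)
    p_t[shared_partner(labels.T)] = min(
        1.0, spec.connection_density_targets + spec.shared_partner_boost)
    tconn = _symmetric_bernoulli(rng, spec.n_targets, p_t)

    norms = np.linalg.norm(V, axis=1, keepdims=True)
    cos = (V / norms) @ (V / norms).T
    sim = cos + (rng.normal(0.0, spec.similarity_noise, size=cos.shape)
                 if spec.similarity_noise > 0 else 0.0)
    sim = np.clip(sim, 0.0, 1.0)

    def features(n: int, n_feat: int, latent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = rng.normal(size=(n, n_feat))
        cols = rng.choice(n_feat, size=spec.latent_dim, replace=False)
        X[:, cols] = spec.latent_feature_scale * latent + rng.normal(
            0.0, 0.1, size=latent.shape)
        return X, cols

    dX, d_latent_cols = features(spec.n_drugs, spec.n_drug_features, U)
    tX, t_latent_cols = features(spec.n_targets, spec.n_target_features, V)

    return DrugWorld(
        drugs=pd.DataFrame({"id": drug_ids, "name": [f"drug-{i}" for i in range(spec.n_drugs)]}),
        targets=pd.DataFrame({"id": target_ids, "name": [f"target-{i}" for i in range(spec.n_targets)]}),
        interactions=inter,
        drug_connections=pd.DataFrame(dconn, index=drug_ids, columns=drug_ids),
        target_connections=pd.DataFrame(tconn, index=target_ids, columns=target_ids),
        target_similarity=pd.DataFrame(sim, index=target_ids, columns=target_ids),
        drug_features=pd.DataFrame(dX, index=drug_ids),
        target_features=pd.DataFrame(tX, index=target_ids),
        latent_drug=U,
        latent_target=V,
        metadata={
            "seed": spec.seed,
            "spec": dataclasses.asdict(spec),
            "drug_latent_columns": d_latent_cols.tolist(),
            "target_latent_columns": t_latent_cols.tolist(),
            "n_positive": int(n_pos),
        },
    )


# ---------------------------------------------------------------------------
# IC50 training panel and mutation counts
# ---------------------------------------------------------------------------

@dataclass
class IC50Panel:
    """Cell-line expression plus per-line per-drug log-IC50 values."""

    expression: pd.DataFrame    # genes x cell lines (shared gene namespace)
    ic50: pd.DataFrame          # cell line x drug, log-IC50
    planted_drug: str
    weights: dict               # per-drug generating linear maps (gene -> weight)


def generate_ic50_panel(expression: pd.DataFrame, cohort_spec: CohortSpec,
                        n_drugs: int = 251, n_lines: int = 300,
                        n_panel_genes: int = 150,
                        planted_sensitive: str = "drug_0001",
                        noise_sd: float = 0.3, seed: int = 0) -> IC50Panel:
    """Generate a cell-line panel whose planted drug is sensitive in high risk.

    Each drug's log-IC50 is a sparse linear function of standardised
    log-expression plus Gaussian noise.  The planted drug's map is the
    negated true risk function of the cohort's signal genes, so imputation
    onto the cohort yields lower IC50 for higher-risk samples.

    The panel measures a reduced gene namespace (the cuproptosis panel plus
    the first ``n_panel_genes`` cohort genes) and carries more cell lines
    than genes, keeping the per-drug ridge problem well-posed.
    """
    if expression.empty:
        raise ValueError("expression matrix is empty")
    drug_names = [f"drug_{i:04d}" for i in range(1, n_drugs + 1)]
    if planted_sensitive not in drug_names:
        raise ValueError(f"unknown drug id: {planted_sensitive}")
    rng = np.random.default_rng(seed)
    keep = list(dict.fromkeys(
        [g for g in cohort_spec.panel_genes if g in expression.index]
        + list(expression.index[:n_panel_genes])))
    expression = expression.loc[keep]
    genes = expression.index
    if n_lines <= len(genes):
        raise ValueError("need more cell lines than panel genes for a "
                         "well-posed ridge problem")
    line_ids = [f"LINE_{i:03d}" for i in range(n_lines)]

    base = np.log2(expression.to_numpy() + 1.0)
    mu, sd = base.mean(axis=1), base.std(axis=1)
    logX = mu[:, None] + np.where(sd == 0, 1.0, sd)[:, None] * rng.normal(
        size=(len(genes), n_lines))
    panel_expr = pd.DataFrame(2.0 ** logX, index=genes, columns=line_ids)

    Z = (logX - logX.mean(axis=1, keepdims=True))
    Z = Z / np.where(Z.std(axis=1, keepdims=True) == 0, 1.0, Z.std(axis=1, keepdims=True))

    weights: dict[str, dict[str, float]] = {}
    ic50 = np.empty((n_lines, n_drugs))
    sig_genes = cohort_spec.panel_genes[: cohort_spec.n_signal_genes]
    sig_idx = [genes.get_loc(g) for g in sig_genes]
    for d, name in enumerate(drug_names):
        if name == planted_sensitive:
            w = {g: -b for g, b in zip(sig_genes, cohort_spec.effect_sizes)}
        else:
            k = rng.integers(2, 6)
            gidx = rng.choice(len(genes), size=k, replace=False)
            w = {genes[i]: float(c) for i, c in zip(gidx, rng.normal(0.0, 0.4, size=k))}
        weights[name] = w
        y = np.zeros(n_lines)
        for g, c in w.items():
            y += c * Z[genes.get_loc(g)]
        ic50[:, d] = 3.0 + y + (rng.normal(0.0, noise_sd, size=n_lines)
                                if noise_sd > 0 else 0.0)
    del sig_idx
    return IC50Panel(expression=panel_expr,
                     ic50=pd.DataFrame(ic50, index=line_ids, columns=drug_names),
                     planted_drug=planted_sensitive, weights=weights)


def generate_mutation_counts(clinical: pd.DataFrame, high_tmb_fraction: float = 0.4,
                             n_genes: int = 60, low_rate: float = 0.05,
                             high_rate: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Per-sample per-gene Poisson mutation counts from a two-rate mixture.

    A ``high_tmb_fraction`` of samples draw from the high-rate process.
    Returns a samples x genes integer DataFrame with attrs['high_tmb'] holding
    the generating membership.
    """
    if clinical.empty:
        raise ValueError("cohort is empty")
    if not (0.0 <= high_tmb_fraction <= 1.0):
        raise ValueError("high_tmb_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(clinical)
    genes = [f"MUT_{i:03d}" for i in range(n_genes)]
    n_high = int(round(high_tmb_fraction * n))
    is_high = np.zeros(n, dtype=bool)
    is_high[rng.choice(n, size=n_high, replace=False)] = True
    # per-gene propensities so the top-mutated genes are stable
    gene_w = rng.dirichlet(np.ones(n_genes)) * n_genes
    rates = np.where(is_high, high_rate, low_rate)[:, None] * gene_w[None, :]
    counts = rng.poisson(rates)
    out = pd.DataFrame(counts, index=clinical.index, columns=genes)
    out.attrs["high_tmb"] = pd.Series(is_high, index=clinical.index)
    return out


# ---------------------------------------------------------------------------
# writers (TSV/CSV/GMT)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(out / "expression.tsv", sep="\t")
    cohort.sample_labels.to_frame().to_csv(out / "sample_labels.tsv", sep="\t")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t")


def write_drug_world(world: DrugWorld, outdir) -> None:
    import json
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world.drugs.to_csv(out / "drugs.csv", index=False)
    world.targets.to_csv(out / "targets.csv", index=False)
    world.interactions.to_csv(out / "interactions.csv", index=False)
    world.drug_connections.to_csv(out / "drug_connections.csv")
    world.target_connections.to_csv(out / "target_connections.csv")
    world.target_similarity.to_csv(out / "target_similarity.csv")
    world.drug_features.to_csv(out / "drug_features.tsv", sep="\t")
    world.target_features.to_csv(out / "target_features.tsv", sep="\t")
    (out / "metadata.json").write_text(json.dumps(world.metadata, indent=1))


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def immune_gene_sets(expression_genes, n_sets: int = 16, set_size: int = 25,
                     seed: int = 0) -> dict[str, list[str]]:
    """Sixteen synthetic immune-cell gene sets drawn from the matrix genes."""
    names = ["aDCs", "B_cells", "CD8_T_cells", "DCs", "iDCs", "Macrophages",
             "Mast_cells", "Neutrophils", "NK_cells", "pDCs", "T_helper_cells",
             "Tfh", "Th1_cells", "Th2_cells", "TIL", "Treg"][:n_sets]
    rng = np.random.default_rng(seed)
    genes = list(expression_genes)
    return {name: sorted(rng.choice(genes, size=min(set_size, len(genes)),
                                    replace=False).tolist())
            for name in names}
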