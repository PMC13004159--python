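"""Synthetic ground truth and assay simulation.

Simulates the measurement chain that the estimators in
:mod:`capmeth.ip` and :mod:`capmeth.captag` invert:

* a transcriptome with per-gene abundance and a true cap-methylated
  fraction ``m_g`` per growth condition (rich vs. minimal medium after
  methionine/SAM starvation);
* an antibody immunoprecipitation arm (m7G-IP) that captures methylated
  caps with efficiency ``eta_ip`` and everything else at a nonspecific
  background rate ``beta_ip``;
* a Cap-Tag arm in which unmethylated caps are enzymatically labeled and
  pulled down with combined efficiency ``lambda_tag`` on top of a
  background ``beta_tag``, with a methyltransferase-omitted (dMTase)
  control that sees only the background, and a fully methylated eGFP
  spike that likewise reports background;
* ERCC spike-in rows appended to every library at fixed known amounts
  (post-enrichment, so they track only library scaling);
* negative-binomial sequencing noise realised as a gamma biological
  factor shared across the fractions of one RNA prep, with Poisson
  counting noise on top (dispersion 0 degenerates to pure Poisson).

Expected molecule counts obey the linear capture model

    IP        ~ A_g * (m_g * eta_ip + (1 - m_g) * beta_ip)
    pulldown  ~ A_g * ((1 - m_g) * lambda_tag + beta_tag)
    dMTase    ~ A_g * beta_tag

so methylated + unmethylated molecules always sum to ``A_g`` (the yeast
model has no third cap state), expected IP signal is strictly increasing
in ``m_g`` whenever ``eta_ip > beta_ip``, and the Cap-Tag pulldown is
strictly decreasing in ``m_g`` whenever ``lambda_tag > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import CountMatrix, ConfigurationError, EGFP_SPIKE_ID, ERCC_PREFIX

__all__ = [
    "GroundTruthParams",
    "AssayConfig",
    "generate_ground_truth",
    "gene_set_table",
    "simulate_libraries",
    "expected_libraries",
    "simulate_bulk_cap",
    "simulate_histone_counts",
    "simulate_occupancy",
    "simulate_ribo",
    "simulate_intron_reads",
]


def _beta_ab(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


@dataclass(frozen=True)
class GroundTruthParams:
    """Defaults describing the simulated transcriptome.

    The starvation preset draws the minimal-medium methylated fraction
    from a two-component Beta mixture: a broad main mode (most
    transcripts partially unmethylated after 1 h of SAM starvation, bulk
    mean ~0.45) plus a smaller high-methylation subpopulation near 0.9.
    Rich-medium methylation is near-complete (uniform on
    ``rich_range``). Abundances are log-normal; induction fold-changes
    (min/rich) are log-normal. About 5% of yeast genes contain an
    intron, with intron lengths a modest fraction of the gene.
    """

    abundance_mean_log: float = float(np.log(10.0))
    abundance_sigma_log: float = 1.2
    induction_sigma_log: float = 0.5
    rich_range: tuple[float, float] = (0.96, 1.0)
    mixture_weights: tuple[float, float] = (0.8, 0.2)
    mixture_means: tuple[float, float] = (0.45, 0.9)
    mixture_conc: tuple[float, float] = (10.0, 20.0)
    intron_gene_frac: float = 0.05
    intron_frac_range: tuple[float, float] = (0.05, 0.35)
    n_terms: int = 12
    terms_per_gene: int = 2
    planted_term: str | None = None
    planted_term_frac: float = 0.05

    @property
    def unmethylated_mean(self) -> float:
        """Population mean of 1 - meth_frac_min under the starvation mixture."""
        w, mu = self.mixture_weights, self.mixture_means
        return 1.0 - (w[0] * mu[0] + w[1] * mu[1]) / (w[0] + w[1])


def generate_ground_truth(
    n_genes: int,
    scenario: str = "starvation",
    seed: int = 0,
    params: GroundTruthParams = GroundTruthParams(),
) -> pd.DataFrame:
    """Draw a per-transcript ground-truth table.

    Returns a DataFrame indexed by gene id with columns
    ``abundance_rich``, ``abundance_min``, ``meth_frac_rich``,
    ``meth_frac_min``, ``intron_frac``, ``first_base`` and ``gene_sets``
    (semicolon-joined annotation-term ids). ``scenario`` is
    ``"rich_only"`` (no starvation shift, minimal-medium methylation
    equals rich) or ``"starvation"`` (mixture-distributed
    ``meth_frac_min``). Reproducible for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if scenario not in ("rich_only", "starvation"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    p = params

    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    abundance_rich = rng.lognormal(p.abundance_mean_log, p.abundance_sigma_log, n_genes)
    induction = rng.lognormal(0.0, p.induction_sigma_log, n_genes)
    abundance_min = abundance_rich * induction
    meth_rich = rng.uniform(*p.rich_range, n_genes)

    # annotation terms first so a planted term can shift the methylation draw
    term_ids = [f"T{i:02d}" for i in range(1, p.n_terms + 1)]
    assign = [
        ";".join(sorted(rng.choice(term_ids, size=p.terms_per_gene, replace=False)))
        for _ in range(n_genes)
    ]
    gene_sets = pd.Series(assign, index=gene_ids)
    planted_mask = np.zeros(n_genes, dtype=bool)
    if p.planted_term is not None:
        k = max(1, int(round(p.planted_term_frac * n_genes)))
        idx = rng.choice(n_genes, size=k, replace=False)
        planted_mask[idx] = True
        gene_sets.iloc[idx] = gene_sets.iloc[idx] + ";" + p.planted_term

    if scenario == "rich_only":
        meth_min = meth_rich.copy()
    else:
        w = np.asarray(p.mixture_weights, dtype=float)
        w = w / w.sum()
        comp = rng.choice(len(w), size=n_genes, p=w)
        meth_min = np.empty(n_genes)
        for c, (mu, conc) in enumerate(zip(p.mixture_means, p.mixture_conc)):
            a, b = _beta_ab(mu, conc)
            sel = comp == c
            meth_min[sel] = rng.beta(a, b, sel.sum())
        if planted_mask.any():
            a, b = _beta_ab(p.mixture_means[1], p.mixture_conc[1])
            meth_min[planted_mask] = rng.beta(a, b, planted_mask.sum())

    intron_frac = np.zeros(n_genes)
    has_intron = rng.random(n_genes) < p.intron_gene_frac
    intron_frac[has_intron] = rng.uniform(*p.intron_frac_range, has_intron.sum())
    first_base = rng.choice(["A", "G"], size=n_genes)

    return pd.DataFrame(
        {
            "abundance_rich": abundance_rich,
            "abundance_min": abundance_min,
            "meth_frac_rich": meth_rich,
            "meth_frac_min": meth_min,
            "intron_frac": intron_frac,
            "first_base": first_base,
            "gene_sets": gene_sets,
        },
        index=gene_ids,
    )


def gene_set_table(truth: pd.DataFrame) -> dict[str, set[str]]:
    """Invert the per-gene ``gene_sets`` column into term -> gene sets."""
    terms: dict[str, set[str]] = {}
    for gid, joined in truth["gene_sets"].items():
        for t in str(joined).split(";"):
            if t:
                terms.setdefault(t, set()).add(str(gid))
    return terms


@dataclass(frozen=True)
class AssayConfig:
    """Capture-chemistry and sequencing parameters for the simulator.

    eta_ip / beta_ip
        Specific and nonspecific capture probabilities of the anti-m7G
        antibody, in (0,1] and [0,1).
    lambda_tag / beta_tag
        Combined ProSeAM-labeling x streptavidin-capture efficiency for
        unmethylated caps and the nonspecific pulldown background.
    dilution
        Cap-Tag input dilution bookkeeping constant (default 22.5,
        matching the %-input formula's divisor).
    depth
        Mean total reads per library (genes + spikes).
    dispersion
        Negative-binomial dispersion phi (Var = mu + phi mu^2); 0 means
        Poisson. Realised as a gamma factor shared by all fractions of
        one biological prep, with Poisson counting on top.
    n_replicates
        Biological replicates per condition and arm.
    n_spikes_ercc / ercc_total_frac
        Number of ERCC rows and their summed amount as a fraction of
        the rich-medium transcriptome (used when ``spike_amounts`` is
        not given explicitly).
    spike_amounts
        Optional explicit ERCC amounts (molecule units).
    egfp_frac
        eGFP spike amount as a fraction of the rich transcriptome.
    """

    eta_ip: float = 0.6
    beta_ip: float = 0.02
    lambda_tag: float = 0.35
    beta_tag: float = 0.01
    dilution: float = 22.5
    depth: float = 2e6
    dispersion: float = 0.1
    n_replicates: int = 2
    n_spikes_ercc: int = 30
    ercc_total_frac: float = 0.02
    spike_amounts: tuple[float, ...] | None = None
    egfp_frac: float = 0.005
    seed: int = 0
    conditions: tuple[str, ...] = ("rich", "min")

    def __post_init__(self) -> None:
        checks = {
            "eta_ip": (self.eta_ip, 0.0 < self.eta_ip <= 1.0),
            "beta_ip": (self.beta_ip, 0.0 <= self.beta_ip < 1.0),
            "lambda_tag": (self.lambda_tag, 0.0 < self.lambda_tag <= 1.0),
            "beta_tag": (self.beta_tag, 0.0 <= self.beta_tag < 1.0),
            "dilution": (self.dilution, self.dilution > 0),
            "depth": (self.depth, self.depth > 0),
            "dispersion": (self.dispersion, self.dispersion >= 0),
            "n_replicates": (self.n_replicates, self.n_replicates >= 1),
        }
        for name, (val, ok) in checks.items():
            if not ok:
                raise ValueError(f"AssayConfig.{name} out of range: {val}")
        if self.n_spikes_ercc < 1 and self.spike_amounts is None:
            raise ConfigurationError("spike configuration missing: need ERCC spikes")


def _ercc_amounts(truth: pd.DataFrame, cfg: AssayConfig) -> pd.Series:
    """Fixed known ERCC amounts: a geometric ladder summing to the configured fraction."""
    if cfg.spike_amounts is not None:
        amounts = np.asarray(cfg.spike_amounts, dtype=float)
        if len(amounts) == 0:
            raise ConfigurationError("spike_amounts is empty")
    else:
        ladder = np.geomspace(1.0, 50.0, cfg.n_spikes_ercc)
        total = cfg.ercc_total_frac * float(truth["abundance_rich"].sum())
        amounts = ladder / ladder.sum() * total
    ids = [f"{ERCC_PREFIX}{i + 1:05d}" for i in range(len(amounts))]
    return pd.Series(amounts, index=pd.Index(ids, name="gene_id"))


def _library_plan(truth: pd.DataFrame, cfg: AssayConfig):
    """Yield (sample_id, meta dict, gene molecules, spike molecules) per library.

    Gene molecule vectors exclude spikes; the gamma biological factor is
    shared within one (assay, condition, replicate) prep across its
    fractions, so the plan groups libraries by prep.
    """
    A = {c: truth[f"abundance_{c}"].to_numpy() for c in cfg.conditions}
    m = {c: truth[f"meth_frac_{c}"].to_numpy() for c in cfg.conditions}
    ercc = _ercc_amounts(truth, cfg)
    egfp_amount = cfg.egfp_frac * float(truth["abundance_rich"].sum())

    plan = []  # list of preps; each prep is a list of library dicts
    for cond in cfg.conditions:
        for rep in range(1, cfg.n_replicates + 1):
            a, mm = A[cond], m[cond]
            ip_prep = [
                dict(
                    sid=f"ip_{cond}_input_{rep}",
                    meta=dict(assay="ip", condition=cond, fraction="input", replicate=rep),
                    genes=a.copy(),
                    spikes=ercc,
                ),
                dict(
                    sid=f"ip_{cond}_ip_{rep}",
                    meta=dict(assay="ip", condition=cond, fraction="ip", replicate=rep),
                    genes=a * (mm * cfg.eta_ip + (1.0 - mm) * cfg.beta_ip),
                    spikes=ercc,
                ),
            ]
            # eGFP (CleanCap, fully methylated) is spiked before Cap-Tag, so it
            # appears in the input and is labeled only at the background rate.
            egfp_in = pd.Series({EGFP_SPIKE_ID: egfp_amount})
            egfp_bg = pd.Series({EGFP_SPIKE_ID: egfp_amount * cfg.beta_tag})
            tag_prep = [
                dict(
                    sid=f"captag_{cond}_input_{rep}",
                    meta=dict(assay="captag", condition=cond, fraction="input", replicate=rep),
                    genes=a.copy(),
                    spikes=pd.concat([egfp_in, ercc]),
                ),
                dict(
                    sid=f"captag_{cond}_pulldown_{rep}",
                    meta=dict(assay="captag", condition=cond, fraction="pulldown", replicate=rep),
                    genes=a * ((1.0 - mm) * cfg.lambda_tag + cfg.beta_tag),
                    spikes=pd.concat([egfp_bg, ercc]),
                ),
                dict(
                    sid=f"captag_{cond}_dmtase_{rep}",
                    meta=dict(assay="captag", condition=cond, fraction="dmtase", replicate=rep),
                    genes=a * cfg.beta_tag,
                    spikes=pd.concat([egfp_bg, ercc]),
                ),
            ]
            plan.append(ip_prep)
            plan.append(tag_prep)
    return plan


def _assemble(truth: pd.DataFrame, cfg: AssayConfig, rng: np.random.Generator | None) -> CountMatrix:
    plan = _library_plan(truth, cfg)
    n_genes = len(truth)
    spike_ids: list[str] = []
    for prep in plan:
        for lib in prep:
            for s in lib["spikes"].index:
                if s not in spike_ids:
                    spike_ids.append(s)
    all_ids = list(truth.index) + spike_ids
    columns: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    for prep in plan:
        if rng is not None and cfg.dispersion > 0:
            shape = 1.0 / cfg.dispersion
            gamma = rng.gamma(shape, cfg.dispersion, n_genes)
        else:
            gamma = np.ones(n_genes)
        for lib in prep:
            spikes = lib["spikes"]
            total = float(lib["genes"].sum() + spikes.sum())
            scale = cfg.depth / total
            mean = np.zeros(len(all_ids))
            mean[:n_genes] = scale * lib["genes"] * gamma
            sp = spikes.reindex(pd.Index(spike_ids), fill_value=0.0).to_numpy()
            mean[n_genes:] = scale * sp
            if rng is not None:
                columns[lib["sid"]] = rng.poisson(mean).astype(np.int64)
            else:
                columns[lib["sid"]] = mean
            meta_rows[lib["sid"]] = lib["meta"]
    counts = pd.DataFrame(columns, index=pd.Index(all_ids, name="gene_id"))
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"
    spike_flag = pd.Series(
        [False] * n_genes + [True] * len(spike_ids), index=counts.index
    )
    return CountMatrix(counts, meta, spike_flag)


def simulate_libraries(truth: pd.DataFrame, cfg: AssayConfig) -> CountMatrix:
    """Simulate sequenced libraries for both assay arms.

    Emits, per condition and replicate: input + IP (m7G-IP arm) and
    input + pulldown + dMTase pulldown (Cap-Tag arm), with ERCC rows in
    every library and the eGFP spike in the Cap-Tag libraries. Counts
    are negative-binomial around the capture-model means, scaled so each
    library's expected total equals ``cfg.depth``.
    """
    rng = np.random.default_rng(cfg.seed)
    return _assemble(truth, cfg, rng)


def expected_libraries(truth: pd.DataFrame, cfg: AssayConfig) -> CountMatrix:
    """Noise-free expected counts (real-valued) under the capture model.

    The exact means the stochastic simulator fluctuates around; used as
    the closed-form oracle for estimator-consistency checks.
    """
    return _assemble(truth, cfg, None)


def simulate_bulk_cap(
    truth: pd.DataFrame,
    condition: str = "min",
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Bulk cap-species amounts (LC-MS-style readout).

    Abundance-weighted totals of methylated (m7GpppN) and unmethylated
    (GpppN) caps, split by the +1 transcribed base (A or G), with
    multiplicative log-normal noise of coefficient of variation
    ``noise_cv`` (mean-preserving). Returns a Series indexed by species
    name in calibrated arbitrary units.
    """
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    rng = np.random.default_rng(seed)
    a = truth[f"abundance_{condition}"]
    m = truth[f"meth_frac_{condition}"]
    amounts = {}
    for base in ("A", "G"):
        sel = truth["first_base"] == base
        amounts[f"m7Gppp{base}"] = float((a[sel] * m[sel]).sum())
        amounts[f"Gppp{base}"] = float((a[sel] * (1.0 - m[sel])).sum())
    s = pd.Series(amounts)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        s = s * np.exp(rng.normal(-0.5 * sigma**2, sigma, len(s)))
    return s


def simulate_histone_counts(
    n_genes: int = 1000,
    n_replicates: int = 3,
    planted_frac: float = 0.1,
    effect: float = 4.0,
    noise_sd_log2: float = 0.15,
    depth: float = 5e5,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Index]:
    """H3K36me3 / total-H3 ChIP count matrix with a planted gain subset.

    A ``planted_frac`` fraction of genes carries an ``effect``-fold gain
    of the K36/H3 ratio in minimal medium; replicate noise is log-normal
    with the given log2 standard deviation, on top of Poisson counting.
    Returns the count matrix (assay ``chip``, fractions ``k36``/``h3``)
    and the planted gene index.
    """
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    base = rng.lognormal(np.log(50.0), 0.8, n_genes)
    ratio_rich = rng.lognormal(0.0, 0.3, n_genes)
    planted = pd.Index(
        rng.choice(n_genes, size=max(1, int(round(planted_frac * n_genes))), replace=False)
    )
    gain = np.ones(n_genes)
    gain[planted] = effect
    ratio_min = ratio_rich * gain

    columns, meta_rows = {}, {}
    ln2 = np.log(2.0)
    for cond, ratio in (("rich", ratio_rich), ("min", ratio_min)):
        for rep in range(1, n_replicates + 1):
            for frac, mol in (("h3", base), ("k36", base * ratio)):
                noisy = mol * np.exp(rng.normal(0.0, noise_sd_log2 * ln2, n_genes))
                scaled = noisy / noisy.sum() * depth
                sid = f"chip_{cond}_{frac}_{rep}"
                columns[sid] = rng.poisson(scaled).astype(np.int64)
                meta_rows[sid] = dict(
                    assay="chip", condition=cond, fraction=frac, replicate=rep
                )
    counts = pd.DataFrame(columns, index=gene_ids)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"
    return CountMatrix(counts, meta), gene_ids[planted]


def simulate_occupancy(
    truth: pd.DataFrame,
    condition: str = "min",
    baseline: float = 0.2,
    noise_sd_log: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene Abd1 peak signal and Pol II gene-body signal.

    Pol II tracks transcription (abundance proxy); Abd1 binding grows
    with the true methylated fraction on top of a transcription-coupled
    component, so relative occupancy (abd1/polII) is a noisy increasing
    function of methylation.
    """
    rng = np.random.default_rng(seed)
    a = truth[f"abundance_{condition}"].to_numpy()
    m = truth[f"meth_frac_{condition}"].to_numpy()
    polii = a * rng.lognormal(0.0, 0.2, len(truth))
    abd1 = polii * (baseline + m) * rng.lognormal(0.0, noise_sd_log, len(truth))
    return pd.DataFrame(
        {"abd1_peak_signal": abd1, "polii_genebody_signal": polii},
        index=truth.index,
    )


def simulate_ribo(
    truth: pd.DataFrame,
    te_sd_log: float = 0.4,
    te_meth_slope: float = 0.3,
    depth: float = 2e6,
    seed: int = 0,
) -> CountMatrix:
    """Ribosome-footprint and mRNA count libraries for both conditions.

    Translation efficiency is log-normal per gene; its starvation shift
    carries a weak positive coupling (``te_meth_slope`` in log2 units
    per unit methylated fraction) to cap methylation, echoing the weak
    correlations seen between TE and cap methylation.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    m = truth["meth_frac_min"].to_numpy()
    te_rich = rng.lognormal(0.0, te_sd_log, n)
    shift = 2.0 ** (te_meth_slope * (m - m.mean()) + rng.normal(0.0, 0.3, n))
    te = {"rich": te_rich, "min": te_rich * shift}
    columns, meta_rows = {}, {}
    for cond in ("rich", "min"):
        a = truth[f"abundance_{cond}"].to_numpy()
        for frac, mol in (("mrna", a), ("footprint", a * te[cond])):
            scaled = mol / mol.sum() * depth
            sid = f"ribo_{cond}_{frac}_1"
            columns[sid] = rng.poisson(scaled).astype(np.int64)
            meta_rows[sid] = dict(assay="ribo", condition=cond, fraction=frac, replicate=1)
    counts = pd.DataFrame(columns, index=truth.index)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"
    return CountMatrix(counts, meta)


def simulate_intron_reads(
    truth: pd.DataFrame,
    cfg: AssayConfig = AssayConfig(),
    condition: str = "min",
    unspliced_frac: float = 0.12,
    unspliced_meth_factor: float = 0.3,
    depth: float = 3e5,
    seed: int = 0,
) -> pd.DataFrame:
    """Intronic/exonic read counts per library class (input, IP, Cap-Tag).

    Intronic reads come only from unspliced pre-mRNA molecules, which
    carry a lower cap-methylated fraction (``unspliced_meth_factor`` x
    the spliced fraction's). Under the capture model this forces the
    intron/exon ratio ordering Cap-Tag > input > IP. Returns a long
    DataFrame with columns ``library_class``, ``gene_id``, ``intronic``,
    ``exonic``.
    """
    rng = np.random.default_rng(seed)
    a = truth[f"abundance_{condition}"].to_numpy()
    m_s = truth[f"meth_frac_{condition}"].to_numpy()
    m_u = m_s * unspliced_meth_factor
    ifrac = truth["intron_frac"].to_numpy()
    u = np.where(ifrac > 0, unspliced_frac, 0.0)

    def capture(klass: str, m: np.ndarray) -> np.ndarray:
        if klass == "input":
            return np.ones_like(m)
        if klass == "ip":
            return m * cfg.eta_ip + (1.0 - m) * cfg.beta_ip
        if klass == "captag":
            return (1.0 - m) * cfg.lambda_tag + cfg.beta_tag
        raise ValueError(klass)

    rows = []
    for klass in ("input", "ip", "captag"):
        c_u, c_s = capture(klass, m_u), capture(klass, m_s)
        intronic = a * u * ifrac * c_u
        exonic = a * (u * (1.0 - ifrac) * c_u + (1.0 - u) * c_s)
        total = intronic.sum() + exonic.sum()
        scale = depth / total
        rows.append(
            pd.DataFrame(
                {
                    "library_class": klass,
                    "gene_id": truth.index,
                    "intronic": rng.poisson(scale * intronic),
                    "exonic": rng.poisson(scale * exonic),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
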