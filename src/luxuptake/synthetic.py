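"""Synthetic-data generators with known ground truth.

Emulates the study design the pipeline targets: a control line plus a
strong and a weak overexpressor of a master phosphate regulator, sampled
at three culture days in triplicate; a two-timepoint reference
phosphate-starvation fold-change dataset in wild-type and regulator-null
mutant backgrounds; coupled biomass growth and nutrient-drawdown
physiology; and fixed-length reads drawn from transgene / endogenous-gene
fragments for fragment-specific quantification.

Ground truth (class labels, directions, per-line true effects, planted
ectopic / regulator-independent calls, growth and uptake parameters) is
returned alongside every dataset so downstream recovery can be quantified.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, FoldChangeTable, PhysiologySeries, sample_id
from .errors import InvalidConfigError, InvalidFragmentError

CLASS_LABELS = ("I", "II", "III", "IV", "null")


@dataclass
class LineSpec:
    """One culture line: overexpression strength 0 marks the control."""

    label: str
    strength: float
    mu: float = 1.4  # specific growth rate, 1/day
    uptake_scale: float = 30.0  # mg P per g dw per day at saturating PE


def default_lines() -> list[LineSpec]:
    return [
        LineSpec("UVM4", 0.0, mu=1.44, uptake_scale=12.0),
        LineSpec("8-27", 1.0, mu=1.33, uptake_scale=80.0),
        LineSpec("8-42", 0.8, mu=1.42, uptake_scale=35.0),
    ]


def default_class_fractions() -> dict[str, float]:
    return {"I": 0.06, "II": 0.20, "III": 0.12, "IV": 0.06, "null": 0.56}


def default_fragment_depths() -> dict[str, int]:
    return {"YFP_CDS": 100, "PSR1_CDS": 80, "PSR1_5UTR": 50, "PSR1_3UTR": 50}


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    class_fractions: dict[str, float] = field(default_factory=default_class_fractions)
    effect_size_log2: float = 2.5
    dispersion: float = 0.05
    lib_size_mean: int = 1_000_000
    seed: int = 0
    lines: list[LineSpec] = field(default_factory=default_lines)
    days: tuple[int, ...] = (2, 3, 6)
    replicates: int = 3
    up_fraction: float = 0.7
    # physiology (daily sampling over `horizon` days)
    horizon: int = 7
    y0: float = 0.001  # inoculum, g dw/L
    capacity: float = 3.0  # carrying capacity, g dw/L
    pe0: float = 30.0  # initial medium PO4-P, mg P/L
    km: float = 5.0  # Monod half-saturation for P uptake, mg P/L
    p_mg_ratio: float = 2.5  # molar P:Mg drawdown ratio
    mg0: float = 15.0  # initial medium Mg, mg/L
    nh4n0: float = 100.0  # initial medium NH4-N, mg N/L
    n_yield: float = 35.0  # mg N consumed per g dw formed
    # reads / fragments
    read_length: int = 75
    fragment_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "YFP_CDS": 300,
            "PSR1_CDS": 400,
            "PSR1_5UTR": 150,
            "PSR1_3UTR": 150,
        }
    )
    fragment_depths: dict[str, int] = field(default_factory=default_fragment_depths)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise InvalidConfigError("n_genes must be positive")
        total = sum(self.class_fractions.get(k, 0.0) for k in CLASS_LABELS)
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(
                f"class_fractions must sum to 1 (got {total!r})"
            )
        if self.dispersion <= 0:
            raise InvalidConfigError("dispersion must be positive")
        if self.lib_size_mean <= 0:
            raise InvalidConfigError("lib_size_mean must be positive")
        if self.replicates < 2:
            raise InvalidConfigError("replicates must be >= 2")
        if list(self.days) != sorted(set(self.days)):
            raise InvalidConfigError("days must be strictly increasing")
        if self.effect_size_log2 <= 0:
            raise InvalidConfigError("effect_size_log2 must be positive")
        strengths = [ln.strength for ln in self.lines]
        if not any(s == 0 for s in strengths):
            raise InvalidConfigError("one line must be the control (strength 0)")
        if sum(s > 0 for s in strengths) < 1:
            raise InvalidConfigError("need at least one overexpressor line")

    @property
    def control(self) -> LineSpec:
        return next(ln for ln in self.lines if ln.strength == 0)

    @property
    def oe_lines(self) -> list[LineSpec]:
        """Overexpressor lines ordered strongest first."""
        oe = [ln for ln in self.lines if ln.strength > 0]
        return sorted(oe, key=lambda ln: -ln.strength)

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    ``genes``: per-gene frame with class_label, direction, in_ref_early,
    in_ref_late, ref_dir_early/late (sign of the planted wild-type
    reference effect), ectopic, independent, regulator_tracking.
    ``log2fc``: genes x (line, day) true log2 fold changes vs control.
    ``line_params``: per-line growth/uptake parameters used by the
    physiology generator.
    """

    genes: pd.DataFrame
    log2fc: pd.DataFrame
    line_params: pd.DataFrame

    def regulated(self) -> pd.Index:
        return self.genes.index[self.genes["class_label"] != "null"]


def _rng_for(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stage)))


def build_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Assign classes, directions, effects and reference/mutant plantings."""
    config.validate()
    rng = _rng_for(config, 0)
    n = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    fracs = np.array([config.class_fractions.get(k, 0.0) for k in CLASS_LABELS])
    counts = np.floor(fracs * n).astype(int)
    counts[-1] = n - counts[:-1].sum()  # remainder to null
    labels = np.repeat(CLASS_LABELS, counts)
    rng.shuffle(labels)

    up = rng.random(n) < config.up_fraction
    direction = np.where(labels == "null", "none", np.where(up, "up", "down"))

    # which genes appear in the wild-type reference dataset, and where
    in_early = np.zeros(n, bool)
    in_late = np.zeros(n, bool)
    for i, lab in enumerate(labels):
        if lab == "I":
            pick = rng.integers(3)  # early, late, or both
            in_early[i] = pick in (0, 2)
            in_late[i] = pick in (1, 2)
        elif lab in ("II", "III") and rng.random() < 0.5:
            pick = rng.integers(3)
            in_early[i] = pick in (0, 2)
            in_late[i] = pick in (1, 2)

    # reference direction mostly matches the overexpression direction
    sign = np.where(direction == "up", 1, -1)
    flip = rng.random(n) < 0.2
    ref_sign = np.where(flip, -sign, sign)

    # planted mutant-background behaviour
    in_ref = in_early | in_late
    ectopic = np.array(["none"] * n, dtype=object)
    independent = np.array(["none"] * n, dtype=object)
    for i, lab in enumerate(labels):
        if lab == "null":
            continue
        if in_ref[i]:
            r = rng.random()
            if r < 0.25:
                independent[i] = "up" if ref_sign[i] > 0 else "down"
            elif r < 0.40:
                # significantly altered from wild type in the mutant
                if rng.random() < 0.5:
                    ectopic[i] = "down" if ref_sign[i] > 0 else "up"  # flipped
                else:
                    ectopic[i] = "up" if ref_sign[i] > 0 else "down"  # amplified
        else:
            if rng.random() < 0.25:
                ectopic[i] = direction[i]

    # true per-line per-day effects: constant over days, scaled by line
    # strength, magnitude jittered around the configured mean effect
    oe = config.oe_lines
    cols = pd.MultiIndex.from_product(
        [[ln.label for ln in oe], list(config.days)], names=["line", "day"]
    )
    log2fc = pd.DataFrame(0.0, index=genes, columns=cols)
    magnitude = config.effect_size_log2 * np.exp(rng.normal(0.0, 0.1, n))
    strong, weak = oe[0], oe[-1] if len(oe) > 1 else oe[0]
    for i, lab in enumerate(labels):
        if lab == "null":
            continue
        affected = {
            "I": [ln.label for ln in oe],
            "IV": [ln.label for ln in oe],
            "II": [strong.label],
            "III": [weak.label],
        }[lab]
        for ln in oe:
            if ln.label not in affected:
                continue
            # Class IV genes respond equally in both lines (no dose
            # dependence on the regulator); other classes scale with
            # overexpression strength
            scale = 1.0 if lab == "IV" else min(1.0, ln.strength)
            eff = sign[i] * max(1.05, magnitude[i] * scale)
            for d in config.days:
                log2fc.loc[genes[i], (ln.label, d)] = eff

    tracking = (labels == "I") & (direction == "up")

    gene_frame = pd.DataFrame(
        {
            "class_label": labels,
            "direction": direction,
            "in_ref_early": in_early,
            "in_ref_late": in_late,
            "ref_dir_early": np.where(in_early, ref_sign, 0),
            "ref_dir_late": np.where(in_late, ref_sign, 0),
            "ectopic": ectopic,
            "independent": independent,
            "regulator_tracking": tracking,
        },
        index=genes,
    )

    line_params = pd.DataFrame(
        {
            "line": [ln.label for ln in config.lines],
            "strength": [ln.strength for ln in config.lines],
            "mu_true": [ln.mu for ln in config.lines],
            "capacity": config.capacity,
            "uptake_scale": [ln.uptake_scale for ln in config.lines],
            "p_mg_ratio": config.p_mg_ratio,
        }
    ).set_index("line")

    return SyntheticTruth(genes=gene_frame, log2fc=log2fc, line_params=line_params)


def generate_counts(
    config: SyntheticConfig, truth: SyntheticTruth | None = None
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial counts with lognormal per-gene baselines.

    Regulated (line, day) cells receive a multiplicative 2**log2fc shift;
    library sizes vary mildly around ``lib_size_mean``.
    """
    config.validate()
    if truth is None:
        truth = build_truth(config)
    rng = _rng_for(config, 1)
    n = config.n_genes

    # the simulated genes carry ~80% of the library; the remainder stands
    # for unannotated reads, so per-sample totals are true library sizes
    # and CPM ratios are unbiased by the planted regulation
    base_mean = 0.8 * config.lib_size_mean / n
    baseline = base_mean * np.exp(rng.normal(0.0, 1.0, n))
    baseline = np.clip(baseline, 5.0, None)

    sids, mus, totals = [], [], []
    for ln in config.lines:
        for d in config.days:
            shift = (
                np.ones(n)
                if ln.strength == 0
                else 2.0 ** truth.log2fc[(ln.label, d)].to_numpy()
            )
            cell_mu = baseline * shift
            for r in range(1, config.replicates + 1):
                lib_factor = np.exp(rng.normal(0.0, 0.05))
                sids.append(sample_id(ln.label, d, r))
                mus.append(cell_mu * lib_factor)
                totals.append(config.lib_size_mean * lib_factor)

    phi = config.dispersion
    out = np.empty((n, len(sids)), dtype=np.int64)
    for j, m in enumerate(mus):
        if phi < 1e-8:
            out[:, j] = rng.poisson(m)
        else:
            nb_n = 1.0 / phi
            out[:, j] = rng.negative_binomial(nb_n, nb_n / (nb_n + m))

    counts = pd.DataFrame(out, index=truth.genes.index, columns=sids)
    return CountMatrix(
        counts=counts, totals=pd.Series(totals, index=sids, dtype=float)
    ), truth


@dataclass
class ReferenceDataset:
    """Reference starvation fold changes in wild-type and mutant backgrounds."""

    wild_type: FoldChangeTable
    mutant: FoldChangeTable


def generate_reference_pstress(
    config: SyntheticConfig, truth: SyntheticTruth
) -> ReferenceDataset:
    """Two-contrast ('early', 'late') reference fold-change tables.

    Wild-type effects honour the planted in-reference flags; mutant
    effects realise the planted ectopic / regulator-independent calls by
    construction: independent genes track the wild type (fold ratio < 2,
    same direction, both significant), ectopic genes are significant in
    the mutant while absent from — or >2-fold altered from — the wild
    type, and all other in-reference genes are silent in the mutant
    (regulator-dependent).
    """
    rng = _rng_for(config, 2)
    genes = truth.genes.index
    rows_wt, rows_mut = [], []
    for g in genes:
        rec = truth.genes.loc[g]
        for contrast, in_flag, rdir in (
            ("early", rec["in_ref_early"], rec["ref_dir_early"]),
            ("late", rec["in_ref_late"], rec["ref_dir_late"]),
        ):
            if in_flag:
                wt = rdir * (1.5 + 0.5 * rng.random())
            else:
                wt = rng.uniform(-0.8, 0.8)
            if rec["independent"] != "none" and in_flag:
                mut = wt + rng.uniform(-0.35, 0.35)
            elif rec["ectopic"] != "none":
                edir = 1.0 if rec["ectopic"] == "up" else -1.0
                if in_flag:
                    if edir == np.sign(wt):
                        mut = wt + edir * (1.2 + 0.3 * rng.random())  # amplified
                    else:
                        mut = edir * (1.5 + 0.5 * rng.random())  # flipped
                else:
                    mut = edir * (1.5 + 0.5 * rng.random())
            else:
                mut = rng.uniform(-0.8, 0.8)
            rows_wt.append((g, contrast, 2.0**wt, wt, np.nan))
            rows_mut.append((g, contrast, 2.0**mut, mut, np.nan))
    cols = ["gene_id", "contrast", "fc", "log2fc", "padj"]
    return ReferenceDataset(
        wild_type=FoldChangeTable(pd.DataFrame(rows_wt, columns=cols), provenance="internal"),
        mutant=FoldChangeTable(pd.DataFrame(rows_mut, columns=cols), provenance="internal"),
    )


def generate_physiology(config: SyntheticConfig) -> PhysiologySeries:
    """Logistic growth with Monod-like daily P drawdown and coupled Mg loss.

    Per day: biomass follows a logistic curve sampled at integer days;
    the medium P drop is ``uptake_scale * biomass * PE/(PE+km)`` floored
    at zero; Mg falls at the P molar rate divided by ``p_mg_ratio``;
    biomass P (% dw) is the cumulative medium P loss divided by biomass
    (mass conservation holds exactly); NH4-N tracks biomass formation.
    """
    config.validate()
    P_MM, MG_MM = 30.97, 24.31
    rows = []
    for ln in config.lines:
        y0, K = config.y0, config.capacity
        pe, mgc = config.pe0, config.mg0
        removed = 0.0
        for d in range(config.horizon + 1):
            biomass = K / (1.0 + (K - y0) / y0 * np.exp(-ln.mu * d))
            if d > 0:
                drop = min(pe, ln.uptake_scale * biomass * pe / (pe + config.km))
                pe -= drop
                removed += drop
                mgc = max(0.0, mgc - (drop / P_MM) / config.p_mg_ratio * MG_MM)
            pi = 0.0 if biomass == 0 else removed / biomass / 10.0  # % dw
            nh4 = max(0.0, config.nh4n0 - config.n_yield * biomass)
            rows.append((ln.label, d, biomass, pe, pi, mgc, nh4))
    frame = pd.DataFrame(
        rows, columns=["line", "day", "biomass", "pe", "pi", "mg", "nh4n"]
    )
    return PhysiologySeries(frame)


_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def generate_reads_and_fragments(
    config: SyntheticConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[str, int]]:
    """Error-free fixed-length reads sampled uniformly from fragments.

    Returns ``(reads, fragments, true_counts)`` where reads/fragments are
    ``(name, sequence)`` pairs. Roughly half the reads are
    reverse-complemented to exercise strand-aware counting. Every read is
    checked to match its source fragment only, so an exact-match counter
    must reproduce ``true_counts`` exactly.
    """
    config.validate()
    rng = _rng_for(config, 3)
    frags: list[tuple[str, str]] = []
    for name, length in config.fragment_lengths.items():
        if length < config.read_length:
            raise InvalidFragmentError(
                f"fragment {name} shorter than read length {config.read_length}"
            )
        frags.append((name, "".join(rng.choice(_BASES, size=length))))
    validate_fragments(frags)

    seqs = {n: s for n, s in frags}
    reads: list[tuple[str, str]] = []
    true_counts: dict[str, int] = {}
    for name, _ in frags:
        depth = int(config.fragment_depths.get(name, 0))
        true_counts[name] = depth
        seq = seqs[name]
        for k in range(depth):
            for _attempt in range(20):
                start = rng.integers(0, len(seq) - config.read_length + 1)
                read = seq[start : start + config.read_length]
                hits = sum(
                    1
                    for s in seqs.values()
                    if read in s or _revcomp(read) in s
                )
                if hits == 1:
                    break
            else:  # pragma: no cover - vanishingly unlikely for random sequence
                raise InvalidFragmentError(
                    f"could not draw an unambiguous read from {name}"
                )
            if rng.random() < 0.5:
                read = _revcomp(read)
            reads.append((f"{name}_read{k}", read))
    return reads, frags, true_counts


def validate_fragments(fragments: list[tuple[str, str]]) -> None:
    """Reject duplicate or substring-nested fragments (either strand)."""
    for i, (ni, si) in enumerate(fragments):
        for j, (nj, sj) in enumerate(fragments):
            if i == j:
                continue
            if si in sj or _revcomp(si) in sj:
                raise InvalidFragmentError(
                    f"fragment {ni} is contained in fragment {nj}"
                )


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SyntheticConfig
    truth: SyntheticTruth
    counts: CountMatrix
    reference: ReferenceDataset
    physiology: PhysiologySeries
    reads: list[tuple[str, str]]
    fragments: list[tuple[str, str]]
    fragment_truth: dict[str, int]


def generate_bundle(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Generate the full study-design bundle under one seed."""
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = config.replace(seed=seed)
    truth = build_truth(config)
    counts, _ = generate_counts(config, truth)
    reference = generate_reference_pstress(config, truth)
    physiology = generate_physiology(config)
    reads, frags, frag_truth = generate_reads_and_fragments(config)
    return SyntheticBundle(
        config=config,
        truth=truth,
        counts=counts,
        reference=reference,
        physiology=physiology,
        reads=reads,
        fragments=frags,
        fragment_truth=frag_truth,
    )
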