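"""Seeded synthetic cohorts with planted differential expression, sponge
modules, a hub node and clinical couplings.

The generator emulates a small two-group sequencing cohort (10 cases vs 5
controls by default) on the normalized-abundance scale: log2 abundances are
Gaussian, planted differentially expressed (DE) genes are mean-shifted in the
case group, and competing-endogenous-RNA (ceRNA) "sponge" structure is induced
by a latent per-sample disease factor shared by all planted modules. Loadings
are solved in closed form so a sponge pair's within-group correlation equals
its target ``r`` in expectation, with the canonical sign pattern
(lncRNA down / miRNA up / mRNA down; lncRNA-miRNA and miRNA-mRNA negative,
lncRNA-mRNA positive). Clinical covariates are linear functions of a named
miRNA's log2 abundance plus noise, calibrated so the realized sample
correlation (on the screen's log2 scale) equals the target exactly.

Identical config and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    ExpressionTable,
    InteractionTable,
    SampleGroups,
    pair_class_for,
)

#: clinical parameter -> (unit, population mean, population sd)
CLINICAL_PARAMETERS = {
    "EF": ("%", 60.0, 8.0),
    "TC": ("mmol/L", 4.8, 0.9),
    "Hcy": ("umol/L", 14.0, 4.0),
    "LDL": ("mmol/L", 2.8, 0.8),
}


class ConfigError(ValueError):
    """The simulation config is internally inconsistent."""


@dataclass(frozen=True)
class SpongeModule:
    """A planted lncRNA-miRNA-mRNA trio sharing the disease factor."""

    lncrna: str
    mirna: str
    mrna: str
    target_r: float = 0.9


@dataclass(frozen=True)
class HubSpec:
    """A planted high-degree miRNA with several lncRNA/mRNA partners."""

    mirna: str = "mir_0001"
    lncrna_partners: tuple[str, ...] = ("lnc_0001", "lnc_0002")
    mrna_partners: tuple[str, ...] = ("mrna_0001", "mrna_0002")
    target_r: float = 0.9


@dataclass
class SimulationConfig:
    seed: int = 0
    n_case: int = 10
    n_control: int = 5
    n_genes: dict[str, int] = field(
        default_factory=lambda: {"lncRNA": 200, "miRNA": 300, "mRNA": 400}
    )
    n_de: dict[str, int] = field(
        default_factory=lambda: {"lncRNA": 50, "miRNA": 75, "mRNA": 100}
    )
    de_log2fc: float = 1.5
    noise_sd: float = 0.5
    sponge_modules: list[SpongeModule] = field(
        default_factory=lambda: [
            SpongeModule("lnc_0003", "mir_0002", "mrna_0003"),
            SpongeModule("lnc_0004", "mir_0003", "mrna_0004"),
        ]
    )
    hub: HubSpec | None = field(default_factory=HubSpec)
    clinical_couplings: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("mir_0001", "EF", -0.85),
            ("mir_0002", "TC", -0.85),
            ("mir_0003", "Hcy", -0.85),
        ]
    )
    decoy_factor: int = 5
    baseline_log2_range: tuple[float, float] = (3.0, 8.0)

    def __post_init__(self) -> None:
        if self.n_case < 3 or self.n_control < 3:
            raise ConfigError("need >= 3 samples per group")
        for cls, k in self.n_de.items():
            if k > self.n_genes.get(cls, 0):
                raise ConfigError(f"n_de exceeds gene count for {cls}")
        for mod in self.sponge_modules:
            if not 0 < mod.target_r < 1:
                raise ConfigError("sponge target |r| must lie in (0, 1)")
        if self.hub is not None and not 0 < self.hub.target_r < 1:
            raise ConfigError("hub target |r| must lie in (0, 1)")
        named = [
            gene
            for mod in self.sponge_modules
            for gene in (mod.lncrna, mod.mirna, mod.mrna)
        ]
        if self.hub is not None:
            named += [self.hub.mirna, *self.hub.lncrna_partners, *self.hub.mrna_partners]
        if len(named) != len(set(named)):
            raise ConfigError("a planted id appears in more than one module role")


@dataclass
class GroundTruth:
    """What was planted: DE genes, sponge edges, the hub, clinical couplings."""

    de_genes: dict[str, str]  # gene -> up/down
    edges: list[tuple[str, str, str]]  # (gene_a, gene_b, pair_class)
    hub: str | None
    clinical: list[tuple[str, str, float]]  # (gene, parameter, target r)

    @property
    def edge_set(self) -> set[tuple[frozenset, str]]:
        return {(frozenset({a, b}), pc) for a, b, pc in self.edges}


@dataclass
class SyntheticDataset:
    lncrna: ExpressionTable
    mirna: ExpressionTable
    mrna: ExpressionTable
    groups: SampleGroups
    interactions: InteractionTable
    clinical: ClinicalTable
    truth: GroundTruth

    @property
    def tables(self) -> dict[str, ExpressionTable]:
        return {"lncRNA": self.lncrna, "miRNA": self.mirna, "mRNA": self.mrna}


_PREFIX = {"lncRNA": "lnc", "miRNA": "mir", "mRNA": "mrna"}
# canonical planted sign pattern: sponge lncRNA/mRNA down, miRNA up
_MODULE_SIGN = {"lncRNA": -1.0, "miRNA": +1.0, "mRNA": -1.0}


def _gene_ids(cls: str, n: int) -> list[str]:
    return [f"{_PREFIX[cls]}_{i + 1:04d}" for i in range(n)]


def _module_members(config: SimulationConfig) -> dict[str, tuple[str, float]]:
    """gene -> (rna_class, factor loading target r)."""
    members: dict[str, tuple[str, float]] = {}
    if config.hub is not None:
        members[config.hub.mirna] = ("miRNA", config.hub.target_r)
        for g in config.hub.lncrna_partners:
            members[g] = ("lncRNA", config.hub.target_r)
        for g in config.hub.mrna_partners:
            members[g] = ("mRNA", config.hub.target_r)
    for mod in config.sponge_modules:
        for g, cls in ((mod.lncrna, "lncRNA"), (mod.mirna, "miRNA"), (mod.mrna, "mRNA")):
            if g in members:
                raise ConfigError(f"planted id {g!r} used twice")
            members[g] = (cls, mod.target_r)
    return members


def planted_edges(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """The sponge/hub pairs the interaction table and network should recover."""
    edges: list[tuple[str, str, str]] = []
    if config.hub is not None:
        for g in config.hub.lncrna_partners:
            edges.append((config.hub.mirna, g, "lncRNA-miRNA"))
        for g in config.hub.mrna_partners:
            edges.append((config.hub.mirna, g, "miRNA-mRNA"))
    for mod in config.sponge_modules:
        edges.append((mod.lncrna, mod.mirna, "lncRNA-miRNA"))
        edges.append((mod.mirna, mod.mrna, "miRNA-mRNA"))
        edges.append((mod.lncrna, mod.mrna, "lncRNA-mRNA"))
    return edges


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate expression tables, groups, interactions, clinical data and truth."""
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_case, config.n_control
    n = n1 + n2
    samples = [f"case_{i + 1:02d}" for i in range(n1)] + [
        f"ctrl_{i + 1:02d}" for i in range(n2)
    ]
    case_mask = np.r_[np.ones(n1), np.zeros(n2)]
    groups = SampleGroups(
        {s: ("case" if m else "control") for s, m in zip(samples, case_mask)}
    )

    members = _module_members(config)
    # the single latent disease factor shared by all planted modules
    z = rng.standard_normal(n)

    tables: dict[str, ExpressionTable] = {}
    de_genes: dict[str, str] = {}
    null_ids: dict[str, list[str]] = {}
    for cls in ("lncRNA", "miRNA", "mRNA"):
        n_g = config.n_genes[cls]
        n_de = config.n_de[cls]
        ids = _gene_ids(cls, n_g)
        # planted module genes occupy the reserved low indices of their class
        reserved = [g for g, (c, _) in members.items() if c == cls]
        for g in reserved:
            if g not in ids[:n_de]:
                raise ConfigError(
                    f"module gene {g!r} must be one of the first {n_de} "
                    f"{cls} ids (planted DE genes)"
                )
        lo, hi = config.baseline_log2_range
        mu = rng.uniform(lo, hi, n_g)
        x = mu[:, None] + config.noise_sd * rng.standard_normal((n_g, n))
        signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
        for i in range(n_de):
            gene = ids[i]
            if gene in members:
                rho = members[gene][1]
                sgn = _MODULE_SIGN[cls]
                signs[i] = sgn
                idio = rng.standard_normal(n)
                x[i] = mu[i] + config.noise_sd * (
                    np.sqrt(rho) * sgn * z + np.sqrt(1.0 - rho) * idio
                )
            x[i] += signs[i] * config.de_log2fc * case_mask
            de_genes[gene] = "up" if signs[i] > 0 else "down"
        unit = "RPM" if cls == "miRNA" else "FPKM"
        tables[cls] = ExpressionTable(
            pd.DataFrame(2.0**x, index=ids, columns=samples), cls, unit
        )
        null_ids[cls] = ids[n_de:]

    edges = planted_edges(config)
    interactions = _interaction_table(config, edges, null_ids, rng)
    clinical = _clinical_table(config, tables, samples, rng)

    truth = GroundTruth(
        de_genes=de_genes,
        edges=edges,
        hub=config.hub.mirna if config.hub is not None else None,
        clinical=list(config.clinical_couplings),
    )
    return SyntheticDataset(
        tables["lncRNA"],
        tables["miRNA"],
        tables["mRNA"],
        groups,
        interactions,
        clinical,
        truth,
    )


def _interaction_table(
    config: SimulationConfig,
    edges: list[tuple[str, str, str]],
    null_ids: dict[str, list[str]],
    rng: np.random.Generator,
) -> InteractionTable:
    """Planted pairs plus decoy pairs drawn among non-planted (null) genes."""
    records = list(edges)
    n_decoys = config.decoy_factor * len(edges)
    class_pairs = [("lncRNA", "miRNA"), ("miRNA", "mRNA"), ("lncRNA", "mRNA")]
    seen = {frozenset({a, b}) for a, b, _ in edges}
    guard = 0
    while len(records) < len(edges) + n_decoys and guard < 100 * n_decoys + 100:
        guard += 1
        ca, cb = class_pairs[rng.integers(len(class_pairs))]
        if not null_ids[ca] or not null_ids[cb]:
            break
        a = null_ids[ca][rng.integers(len(null_ids[ca]))]
        b = null_ids[cb][rng.integers(len(null_ids[cb]))]
        key = frozenset({a, b})
        if key in seen:
            continue
        seen.add(key)
        records.append((a, b, pair_class_for(ca, cb)))
    return InteractionTable.from_records(records)


def _clinical_table(
    config: SimulationConfig,
    tables: dict[str, ExpressionTable],
    samples: list[str],
    rng: np.random.Generator,
) -> ClinicalTable:
    n = len(samples)
    coupled = {param: (gene, r) for gene, param, r in config.clinical_couplings}
    data = {}
    for param, (unit, mean, sd) in CLINICAL_PARAMETERS.items():
        if param in coupled:
            gene, target_r = coupled[param]
            row = None
            for table in tables.values():
                if gene in table.data.index:
                    row = table.data.loc[gene].to_numpy()
                    break
            if row is None:
                raise ConfigError(f"clinical coupling names unknown gene {gene!r}")
            # couple on the same log2(x + pseudocount) scale the clinical
            # screen correlates on, so the realized sample r is exact
            row = np.log2(row + 0.25)
            v = (row - row.mean()) / row.std()
            eps = rng.standard_normal(n)
            # orthogonalize in-sample so the realized correlation is exact
            eps = eps - eps.mean() - (eps * v).mean() / (v * v).mean() * v
            eps_sd = eps.std()
            if eps_sd > 0:
                eps = eps / eps_sd
            latent = target_r * v + np.sqrt(1.0 - target_r**2) * eps
            data[param] = mean + sd * latent
        else:
            data[param] = mean + sd * rng.standard_normal(n)
    return ClinicalTable(pd.DataFrame(data, index=samples))


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A config with no planted structure: both groups identically distributed."""
    defaults = dict(
        seed=seed,
        n_de={"lncRNA": 0, "miRNA": 0, "mRNA": 0},
        sponge_modules=[],
        hub=None,
        clinical_couplings=[],
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


TRUTH_COLUMNS = ["record_type", "field_1", "field_2", "field_3"]


def truth_report(truth: GroundTruth, path) -> None:
    """Write the planted structure as a four-column TSV."""
    rows: list[dict[str, str]] = []
    for gene, direction in truth.de_genes.items():
        rows.append(
            {"record_type": "de_gene", "field_1": gene, "field_2": direction, "field_3": ""}
        )
    for a, b, pair_class in truth.edges:
        rows.append(
            {"record_type": "edge", "field_1": a, "field_2": b, "field_3": pair_class}
        )
    if truth.hub is not None:
        rows.append(
            {"record_type": "hub", "field_1": truth.hub, "field_2": "", "field_3": ""}
        )
    for gene, param, r in truth.clinical:
        rows.append(
            {
                "record_type": "clinical",
                "field_1": gene,
                "field_2": param,
                "field_3": f"{r:.6g}",
            }
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_report(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    de = {
        r.field_1: r.field_2
        for r in df[df.record_type == "de_gene"].itertuples()
    }
    edges = [
        (r.field_1, r.field_2, r.field_3)
        for r in df[df.record_type == "edge"].itertuples()
    ]
    hubs = df[df.record_type == "hub"]["field_1"].tolist()
    clinical = [
        (r.field_1, r.field_2, float(r.field_3))
        for r in df[df.record_type == "clinical"].itertuples()
    ]
    return GroundTruth(de, edges, hubs[0] if hubs else None, clinical)
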