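"""Synthetic multi-omic drug-response cohorts with a planted, recoverable signal.

Real drug-screen data (DepMap omics + CTRPv2 dose-response) is GPU-scale and
external; this module generates desk-scale stand-ins that preserve the
properties the framework is built around:

* the heavy right-skew of the AAC target — a two-component Beta mixture whose
  defaults are calibrated so 1e5 draws have mean ~0.145 and median ~0.091,
  matching the published CTRPv2 summary statistics;
* multi-omic block structure — cell lines share a panel partitioned into
  lineages, features correlate within small blocks, lineages shift block
  means;
* a planted interaction — AAC gains ``beta * (probit of one causal omic
  feature) * (drug carries a named substructure)``, so signal recovery,
  fusion benefit and attribution can all be verified against ground truth.

Drugs come from a hard-coded fixture of valid SMILES spanning many
Bemis-Murcko scaffolds, so scaffold-based splitting is deterministic and
chemically meaningful. The planted drug substructure is the acryloyl /
acrylamide warhead (SMARTS ``C=CC(=O)N``) carried by covalent kinase
inhibitors such as ibrutinib.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from rdkit import Chem

from .core_data import DrugRecord, OmicMatrix, OmicType, ResponseRecord

__all__ = [
    "BetaMixture", "DEFAULT_SKEW", "SyntheticConfig", "GroundTruth",
    "generate_cohort", "generate_dose_response", "aac_from_viability",
    "FIXTURE_DRUGS", "ACRYLOYL_SMARTS",
]

ACRYLOYL_SMARTS = "C=CC(=O)N"

# (name, SMILES, targeted) — ≥40 valid structures over many Murcko scaffolds.
# Approved lineages are attached at cohort-generation time so they match the
# generated lineage panel.
FIXTURE_DRUGS: list[tuple[str, str, bool]] = [
    # acrylamide-bearing covalent kinase inhibitors (planted substructure)
    ("ibrutinib", "C=CC(=O)N1CCCC(C1)n1nc(-c2ccc(Oc3ccccc3)cc2)c2c(N)ncnc21", True),
    ("afatinib", "CN(C)C/C=C/C(=O)Nc1cc2c(Nc3ccc(F)c(Cl)c3)ncnc2cc1OC1CCOC1", True),
    ("osimertinib", "C=CC(=O)Nc1cc(Nc2nccc(-c3cn(C)c4ccccc34)n2)c(OC)cc1N(C)CCN(C)C", True),
    ("acrylamide-probe-1", "C=CC(=O)Nc1ccc(F)cc1", True),
    ("acrylamide-probe-2", "C=CC(=O)Nc1ccc(Cl)cc1", True),
    ("acrylamide-probe-3", "COc1ccc(NC(=O)C=C)cc1", True),
    ("acrylamide-probe-4", "C=CC(=O)N1CCN(c2ccccc2)CC1", True),
    ("acrylamide-probe-5", "C=CC(=O)N1CCCC1", False),
    ("acrylamide-probe-6", "C=CC(=O)Nc1cccnc1", True),
    ("acrylamide-probe-7", "C=CC(=O)Nc1ccc2ccccc2c1", True),
    # targeted, no warhead
    ("imatinib", "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1", True),
    ("gefitinib", "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1", True),
    ("erlotinib", "COCCOc1cc2ncnc(Nc3cccc(C#C)c3)c2cc1OCCOC", True),
    ("sorafenib", "CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(c3)C(F)(F)F)cc2)ccn1", True),
    ("dasatinib", "Cc1nc(Nc2ncc(s2)C(=O)Nc2c(C)cccc2Cl)cc(n1)N1CCN(CCO)CC1", True),
    ("tamoxifen", "CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1", True),
    ("celecoxib", "Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F", True),
    ("methotrexate", "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(cc1)C(=O)NC(CCC(O)=O)C(O)=O", True),
    # untargeted cytotoxics / classics
    ("chlorambucil", "OC(=O)CCCc1ccc(N(CCCl)CCCl)cc1", False),
    ("melphalan", "NC(Cc1ccc(cc1)N(CCCl)CCCl)C(O)=O", False),
    ("cyclophosphamide", "ClCCN(CCCl)P1(=O)NCCCO1", False),
    ("busulfan", "CS(=O)(=O)OCCCCOS(C)(=O)=O", False),
    ("hydroxyurea", "NC(=O)NO", False),
    ("fluorouracil", "Fc1c[nH]c(=O)[nH]c1=O", False),
    ("cytarabine", "NC1=NC(=O)N(C=C1)C1OC(CO)C(O)C1O", False),
    # broad pharmacopeia filler (valid, scaffold-diverse)
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", False),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1", False),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", False),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O", False),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", False),
    ("theophylline", "Cn1c(=O)c2[nH]cnc2n(C)c1=O", False),
    ("nicotine", "CN1CCCC1c1cccnc1", False),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O", False),
    ("coumarin", "O=c1ccc2ccccc2o1", False),
    ("diazepam", "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21", False),
    ("chloroquine", "CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12", True),
    ("indomethacin", "COc1ccc2c(c1)c(CC(O)=O)c(C)n2C(=O)c1ccc(Cl)cc1", False),
    ("diclofenac", "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl", False),
    ("phenytoin", "O=C1NC(=O)C(N1)(c1ccccc1)c1ccccc1", False),
    ("carbamazepine", "NC(=O)N1c2ccccc2C=Cc2ccccc21", False),
    ("metformin", "CN(C)C(=N)NC(N)=N", False),
    ("valproic-acid", "CCCC(CCC)C(O)=O", False),
    ("gabapentin", "NCC1(CC(O)=O)CCCCC1", False),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12", False),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1", False),
    ("lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C", False),
    ("procaine", "CCN(CC)CCOC(=O)c1ccc(N)cc1", False),
    ("isoniazid", "NNC(=O)c1ccncc1", False),
    ("pyrazinamide", "NC(=O)c1cnccn1", False),
    ("sulfanilamide", "Nc1ccc(cc1)S(N)(=O)=O", False),
]


@dataclass(frozen=True)
class BetaMixture:
    """Two-component Beta mixture for the skewed AAC base distribution."""

    weights: tuple[float, float] = (0.8511, 0.1489)
    a: tuple[float, float] = (0.7498, 2.79)
    b: tuple[float, float] = (6.42, 4.63)

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1; got {self.weights}")
        if min(self.weights) < 0 or min(self.a + self.b) <= 0:
            raise ValueError("mixture weights must be >=0 and shapes > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        first = rng.random(n) < self.weights[0]
        draws0 = rng.beta(self.a[0], self.b[0], n)
        draws1 = rng.beta(self.a[1], self.b[1], n)
        return np.where(first, draws0, draws1)

    def mean(self) -> float:
        return sum(w * a / (a + b)
                   for w, a, b in zip(self.weights, self.a, self.b))

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(w * _sps.beta.cdf(x, a, b)
                   for w, a, b in zip(self.weights, self.a, self.b))

    def ppf(self, q) -> np.ndarray:
        """Quantile function via inversion of the CDF on a fine grid."""
        grid = np.linspace(0.0, 1.0, 4001)
        return np.interp(np.asarray(q, dtype=float), self.cdf(grid), grid)


#: Defaults calibrated (scripts/calibrate_skew.py) so that large samples match
#: the CTRPv2 AAC summary: mean 0.145, median 0.091.
DEFAULT_SKEW = BetaMixture()


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort; the seed fully determines the output."""

    n_cell_lines: int = 100
    n_lineages: int = 5
    features_per_omic: dict = field(default_factory=lambda: {
        OmicType.EXP: 40, OmicType.CNV: 30, OmicType.MUT: 20, OmicType.RPPA: 20,
    })
    n_drugs: int = 40
    skew: BetaMixture = field(default_factory=BetaMixture)
    beta: float = 0.3          # planted interaction strength on the AAC scale
    noise_sd: float = 0.03     # residual AAC noise
    # share of the base draw's latent (copula) variance carried by a per-drug
    # main effect; drug identity dominates AAC variance in real screens
    drug_effect_share: float = 0.75
    block_size: int = 5        # intra-omic correlated feature blocks
    block_corr: float = 0.5
    lineage_shift_sd: float = 0.4
    mut_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.features_per_omic = {OmicType(k): int(v)
                                  for k, v in self.features_per_omic.items()}
        if min(self.n_cell_lines, self.n_lineages, self.n_drugs) < 1:
            raise ValueError("all counts must be >= 1")
        if any(v < 1 for v in self.features_per_omic.values()):
            raise ValueError("features_per_omic values must be >= 1")
        if self.n_drugs > len(FIXTURE_DRUGS):
            raise ValueError(
                f"n_drugs <= {len(FIXTURE_DRUGS)} (built-in fixture size)")
        if not (0.0 <= self.block_corr < 1.0):
            raise ValueError("block_corr must be in [0, 1)")
        if not (0.0 <= self.drug_effect_share < 1.0):
            raise ValueError("drug_effect_share must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery tests."""

    causal_omic: OmicType
    causal_feature: str
    causal_feature_index: int
    substructure_smarts: str
    drugs_with_substructure: list[str]
    beta: float


def _gaussian_block_matrix(n_rows: int, n_features: int, block_size: int,
                           corr: float, lineage_of_row: np.ndarray,
                           lineage_shift_sd: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Rows ~ N(lineage shift, 1) with equicorrelated feature blocks."""
    n_blocks = int(np.ceil(n_features / block_size))
    shared = rng.standard_normal((n_rows, n_blocks))
    own = rng.standard_normal((n_rows, n_features))
    block_of = np.minimum(np.arange(n_features) // block_size, n_blocks - 1)
    values = (np.sqrt(corr) * shared[:, block_of]
              + np.sqrt(1.0 - corr) * own)
    n_lineages = int(lineage_of_row.max()) + 1
    shifts = rng.normal(0.0, lineage_shift_sd, (n_lineages, n_blocks))
    values += shifts[lineage_of_row][:, block_of]
    return values


def generate_cohort(config: SyntheticConfig):
    """Generate ``(omic matrices, drug catalog, response records, ground truth)``.

    AAC = clip(base + beta * u_cell * s_drug + noise, 0, 1) where ``u_cell``
    is the probit transform of the causal omic feature (uniform on [0, 1] by
    construction) and ``s_drug`` indicates the acryloyl SMARTS. One response
    record per (cell line, drug) pair.

    The base draw's marginal is exactly the configured Beta-mixture skew
    model, but it is drawn through a Gaussian copula whose latent carries a
    per-drug main effect (``drug_effect_share`` of the z-variance): some
    compounds are broadly potent and some broadly inert, as in real screens,
    which gives a learner a legitimate drug-identity signal while keeping the
    base independent of all omic features. The per-drug effect is itself a
    random linear function of the compound's circular fingerprint (a
    synthetic structure-activity relationship), so structurally similar
    drugs have similar potencies and structure-based encoders can learn it.
    """
    rng = np.random.default_rng(config.seed)
    cell_lines = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    lineage_of_row = np.arange(config.n_cell_lines) % config.n_lineages
    lineage_names = [f"LIN{i:02d}" for i in range(config.n_lineages)]

    matrices: list[OmicMatrix] = []
    causal_raw = None
    causal_omic = None
    for omic_type, n_feat in config.features_per_omic.items():
        values = _gaussian_block_matrix(
            config.n_cell_lines, n_feat, config.block_size, config.block_corr,
            lineage_of_row, config.lineage_shift_sd, rng)
        if omic_type is OmicType.MUT:
            values = (values > _sps.norm.ppf(1.0 - config.mut_rate)).astype(float)
        elif causal_raw is None:
            causal_raw = values[:, 0].copy()
            causal_omic = omic_type
        names = [f"{omic_type.value}_F{j:03d}" for j in range(n_feat)]
        matrices.append(OmicMatrix(omic_type, list(cell_lines), names, values))
    if causal_raw is None:
        raise ValueError("need at least one continuous (non-MUT) omic type "
                         "to plant the causal feature")

    pattern = Chem.MolFromSmarts(ACRYLOYL_SMARTS)
    catalog: list[DrugRecord] = []
    substructure_flags: dict[str, bool] = {}
    for name, smiles, targeted in FIXTURE_DRUGS[:config.n_drugs]:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # fixture is hand-curated; guard anyway
            raise ValueError(f"fixture SMILES failed to parse: {name}")
        substructure_flags[name] = mol.HasSubstructMatch(pattern)
        approved: frozenset[str] = frozenset()
        if targeted:
            k = int(rng.integers(1, 3))
            approved = frozenset(
                rng.choice(lineage_names, size=min(k, len(lineage_names)),
                           replace=False).tolist())
        catalog.append(DrugRecord(name, smiles, targeted, approved))

    # planted per-cell-line score: probit transform -> uniform in [0, 1]
    u_cell = _sps.norm.cdf(causal_raw)

    n_pairs = config.n_cell_lines * config.n_drugs
    rho = config.drug_effect_share
    # synthetic structure-activity relationship: potency = sparse linear
    # function of shared circular-fingerprint bits (a pharmacophore-style
    # QSAR), standardized across the drug panel
    from .drug_graphs import ecfp as _ecfp
    fp = np.vstack([_ecfp(d.smiles, 2, 256) for d in catalog])
    freq = fp.mean(axis=0)
    shared = np.flatnonzero((freq >= 0.1) & (freq <= 0.9))
    k = min(16, shared.size)
    qsar_bits = rng.choice(shared, size=k, replace=False) if k else np.array([], int)
    qsar_w = rng.standard_normal(k)
    raw = fp[:, qsar_bits] @ qsar_w if k else rng.standard_normal(len(catalog))
    # decorrelate potency from the planted-warhead flag so the interaction
    # term stays identifiable and top-range clipping stays rare
    s_flag = np.array([float(substructure_flags[d.name]) for d in catalog])
    if s_flag.std() > 0:
        raw = raw - s_flag * (np.cov(raw, s_flag)[0, 1] / s_flag.var())
    drug_z = (raw - raw.mean()) / max(raw.std(), 1e-12)
    pair_z = rng.standard_normal(n_pairs)
    z = (np.sqrt(rho) * np.tile(drug_z, config.n_cell_lines)
         + np.sqrt(1.0 - rho) * pair_z)
    base = config.skew.ppf(_sps.norm.cdf(z))
    noise = rng.normal(0.0, config.noise_sd, n_pairs)
    records: list[ResponseRecord] = []
    k = 0
    for i, cl in enumerate(cell_lines):
        for drug in catalog:
            s = 1.0 if substructure_flags[drug.name] else 0.0
            aac = base[k] + config.beta * u_cell[i] * s + noise[k]
            records.append(ResponseRecord(
                cl, drug.name, float(np.clip(aac, 0.0, 1.0)),
                lineage_names[lineage_of_row[i]]))
            k += 1

    causal_matrix = next(m for m in matrices if m.omic_type is causal_omic)
    truth = GroundTruth(
        causal_omic=causal_omic,
        causal_feature=causal_matrix.feature_names[0],
        causal_feature_index=0,
        substructure_smarts=ACRYLOYL_SMARTS,
        drugs_with_substructure=sorted(n for n, f in substructure_flags.items() if f),
        beta=config.beta,
    )
    return matrices, catalog, records, truth


# ---------------------------------------------------------------------------
# dose-response utility (makes the AAC target concrete)
# ---------------------------------------------------------------------------

def aac_from_viability(doses, viability) -> float:
    """AAC = 1 - trapezoidal mean viability over the log10-dose range."""
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.size < 2:
        raise ValueError("need at least 2 doses")
    if not np.all(np.diff(doses) > 0):
        raise ValueError("doses must be strictly increasing")
    log_d = np.log10(doses)
    mean_v = np.trapezoid(viability, log_d) / (log_d[-1] - log_d[0])
    return float(1.0 - mean_v)


def generate_dose_response(ec50: float, hill: float, doses):
    """Viability from a descending Hill curve plus its AAC summary.

    viability(d) = 1 / (1 + (d / ec50)^hill), in [0, 1] for hill > 0.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size < 2:
        raise ValueError("need at least 2 doses")
    if not np.all(np.diff(doses) > 0):
        raise ValueError("doses must be strictly increasing")
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    viability = 1.0 / (1.0 + (doses / ec50) ** hill)
    return viability, aac_from_viability(doses, viability)
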