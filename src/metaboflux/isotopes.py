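"""Forward simulation of [U-13C]-glucose label propagation.

An isotopic steady-state model of glycolysis feeding the TCA cycle, at
mass (isotopolog) resolution. Fully labeled glucose yields M+3 pyruvate;
pyruvate enters the cycle through pyruvate dehydrogenase (PDH, losing one
carbon as CO2 and yielding an M+2 acetyl unit) or pyruvate carboxylase
(PC, fixing unlabeled CO2 and yielding M+3 oxaloacetate). Citrate is the
condensation of the two moieties; the two oxidative decarboxylations of
the span citrate -> succinate remove carbons from the OAA-derived moiety.

Model state and parameters
--------------------------
Pyruvate is M+3 with probability q = f_glc_labeled * (1 - pyr_dilution),
else M+0; lactate mirrors pyruvate. The citrate-synthase acetyl influx is a
mixture of PDH-derived acetyl (weight ``phi_pdh``; M+2 iff the source
pyruvate was M+3) and acetyl from unlabeled fuels such as fatty-acid
oxidation (weight ``1 - phi_pdh``), so the labeled-acetyl probability is
q * phi_pdh. Fresh (non-recycled) OAA influx mixes PC-derived OAA (flux
weight ``phi_pc``; M+3 iff the source pyruvate was M+3) with unlabeled
anaplerotic influx (flux weight ``u_anaplerotic * (1 - phi_pc)``), giving a
labeled-OAA probability q * phi_pc / (phi_pc + u_anaplerotic * (1 -
phi_pc)). The total OAA pool is ``cycling_weight`` recycled malate (label
propagated through a full turn) plus ``1 - cycling_weight`` fresh influx.
These flux-ratio weights make the citrate M+2 / pyruvate M+3 ratio strictly
increasing in phi_pdh and the citrate M+3 / pyruvate M+3 ratio increasing
in phi_pc, which is the property the surrogate-ratio readouts rely on.

Within a moiety, carbon positions are treated as exchangeable: a
decarboxylation removes a labeled carbon with probability
(labeled count) / (moiety size). This avoids full positional-isotopomer
bookkeeping while preserving the M+2/M+3 mass logic; the Monte-Carlo
oracle samples molecules under the same atom rules and bounds the
approximation. CO2 refixed by PC is assumed unlabeled. Glutamate is a
``glu_exchange`` : ``1 - glu_exchange`` mixture of alpha-ketoglutarate and
an unlabeled pool; aspartate mirrors OAA. Succinate symmetry needs no
special handling at mass resolution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sita import MIDProfile, IsotopologSpectrum, correction_matrix

METABOLITES = {
    "pyruvate": 3,
    "lactate": 3,
    "citrate": 6,
    "alpha-ketoglutarate": 5,
    "succinate": 4,
    "fumarate": 4,
    "malate": 4,
    "aspartate": 4,
    "glutamate": 5,
}


@dataclass(frozen=True)
class LabelNetworkConfig:
    """Ground-truth fluxes and label fractions for the simulator.

    All fractions live in [0, 1]; phi_pdh + phi_pc <= 1 (the remainder of
    pyruvate goes to lactate). ``seed`` is used only by the Monte-Carlo
    oracle.
    """

    f_glc_labeled: float = 1.0
    pyr_dilution: float = 0.2
    phi_pdh: float = 0.6
    phi_pc: float = 0.15
    u_anaplerotic: float = 0.5
    cycling_weight: float = 0.2
    glu_exchange: float = 0.6
    tol: float = 1e-12
    max_iters: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "f_glc_labeled",
            "pyr_dilution",
            "phi_pdh",
            "phi_pc",
            "u_anaplerotic",
            "cycling_weight",
            "glu_exchange",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.phi_pdh + self.phi_pc > 1.0 + 1e-12:
            raise ValueError("phi_pdh + phi_pc must be <= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    @property
    def q_pyruvate(self) -> float:
        """Probability that a pyruvate molecule is fully labeled (M+3)."""
        return self.f_glc_labeled * (1.0 - self.pyr_dilution)

    @property
    def q_acetyl(self) -> float:
        """Probability that a citrate acetyl moiety is labeled (M+2)."""
        return self.q_pyruvate * self.phi_pdh

    @property
    def q_fresh_oaa(self) -> float:
        """Probability that a fresh (non-recycled) OAA molecule is M+3."""
        w_pc = self.phi_pc
        w_un = self.u_anaplerotic * (1.0 - self.phi_pc)
        if w_pc + w_un == 0.0:
            return 0.0
        return self.q_pyruvate * w_pc / (w_pc + w_un)


@dataclass(frozen=True)
class MoietyState:
    """Joint distribution of citrate's labeled carbons.

    ``joint[a, b]`` is the probability of ``a`` labeled acetyl-derived
    carbons (0..2) and ``b`` labeled OAA-derived carbons (0..4); kept
    jointly because the TCA decarboxylations remove OAA-moiety carbons.
    """

    joint: np.ndarray  # shape (3, 5)

    def __post_init__(self) -> None:
        arr = np.asarray(self.joint, dtype=float)
        object.__setattr__(self, "joint", arr)
        if arr.shape != (3, 5):
            raise ValueError("citrate joint state must have shape (3, 5)")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("joint probabilities must sum to 1")

    def mid(self) -> np.ndarray:
        out = np.zeros(7)
        for a in range(3):
            for b in range(5):
                out[a + b] += self.joint[a, b]
        return out


def _lose_one(dist: np.ndarray, moiety_size: int) -> np.ndarray:
    """Distribution of labeled count after losing one carbon of the moiety."""
    n_out = len(dist) - 1
    out = np.zeros(n_out)
    for b, p in enumerate(dist):
        if p == 0.0:
            continue
        p_lab = b / moiety_size  # b == moiety_size forces a labeled loss
        if b > 0:
            out[b - 1] += p * p_lab
        if b < n_out:
            out[b] += p * (1.0 - p_lab)
    return out


def _acetyl_dist(cfg: LabelNetworkConfig) -> np.ndarray:
    return np.array([1.0 - cfg.q_acetyl, 0.0, cfg.q_acetyl])


def _fresh_oaa_dist(cfg: LabelNetworkConfig) -> np.ndarray:
    q = cfg.q_fresh_oaa
    return np.array([1.0 - q, 0.0, 0.0, q, 0.0])


def _turn(cfg: LabelNetworkConfig, oaa: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One TCA turn: returns (alpha-KG OAA-moiety dist b1, succinate-level
    dist b2, recycled-OAA dist) given the current OAA labeled-count dist."""
    b1 = _lose_one(oaa, 4)  # citrate -> alpha-KG decarboxylation
    b2 = _lose_one(b1, 3)  # alpha-KG -> succinyl-CoA decarboxylation
    recycled = np.convolve(_acetyl_dist(cfg), b2)  # malate mass -> new OAA labels
    return b1, b2, recycled


def _solve_oaa(cfg: LabelNetworkConfig) -> np.ndarray:
    """Converged OAA labeled-count distribution (fixed-point iteration)."""
    fresh = _fresh_oaa_dist(cfg)
    c = cfg.cycling_weight
    oaa = fresh.copy()
    residual = np.inf
    for _ in range(cfg.max_iters):
        _, _, recycled = _turn(cfg, oaa)
        new = c * recycled + (1.0 - c) * fresh
        residual = float(np.abs(new - oaa).max())
        oaa = new
        if residual < cfg.tol:
            return oaa
    raise RuntimeError(
        f"OAA fixed point did not converge within {cfg.max_iters} iterations "
        f"(residual {residual:.3g} > tol {cfg.tol:.3g})"
    )


def simulate_mids(cfg: LabelNetworkConfig) -> dict[str, MIDProfile]:
    """Steady-state MIDs of glycolytic and TCA metabolites.

    Solves the OAA labeled-count distribution by fixed-point iteration
    (the recycled-malate contribution makes it self-referential), then
    derives every metabolite MID from the converged state. Raises if the
    residual does not drop below ``cfg.tol`` within ``cfg.max_iters``.
    """
    oaa = _solve_oaa(cfg)
    acetyl = _acetyl_dist(cfg)
    b1, b2, _ = _turn(cfg, oaa)
    q = cfg.q_pyruvate

    pyruvate = np.array([1.0 - q, 0.0, 0.0, q])
    citrate = np.convolve(acetyl, oaa)
    akg = np.convolve(acetyl, b1)
    succ = np.convolve(acetyl, b2)
    glut = cfg.glu_exchange * akg + (1.0 - cfg.glu_exchange) * np.eye(len(akg))[0]

    mids = {
        "pyruvate": pyruvate,
        "lactate": pyruvate.copy(),
        "citrate": citrate,
        "alpha-ketoglutarate": akg,
        "succinate": succ,
        "fumarate": succ.copy(),
        "malate": succ.copy(),
        "aspartate": oaa.copy(),
        "glutamate": glut,
    }
    return {name: MIDProfile(name, v / v.sum()) for name, v in mids.items()}


def citrate_joint_state(cfg: LabelNetworkConfig) -> MoietyState:
    """Converged joint (acetyl, OAA) labeled-count distribution of citrate."""
    return MoietyState(np.outer(_acetyl_dist(cfg), _solve_oaa(cfg)))


def mc_oracle(
    cfg: LabelNetworkConfig, n_molecules: int, seed: int | None = None
) -> dict[str, MIDProfile]:
    """Empirical MIDs from sampling individual molecules through the same
    atom rules; the independent cross-check for :func:`simulate_mids`.

    Maintains a population of OAA molecules and iterates the recycling
    mixture until the initial condition is forgotten (``cycling_weight**k``
    below 1e-6, capped at 500 iterations).
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = int(n_molecules)
    q = cfg.q_pyruvate
    q_ac = cfg.q_acetyl
    q_oaa = cfg.q_fresh_oaa
    c = cfg.cycling_weight

    def sample_fresh(k: int) -> np.ndarray:
        return 3 * (rng.random(k) < q_oaa).astype(np.int64)

    def sample_acetyl(k: int) -> np.ndarray:
        return 2 * (rng.random(k) < q_ac).astype(np.int64)

    def lose_one(b: np.ndarray, size: int) -> np.ndarray:
        return b - (rng.random(len(b)) < b / size).astype(np.int64)

    if c == 0:
        n_iter = 1
    else:
        n_iter = min(500, max(2, int(np.ceil(np.log(1e-6) / np.log(c)))))

    oaa = sample_fresh(n)
    for _ in range(n_iter):
        a = sample_acetyl(n)
        b1 = lose_one(oaa, 4)
        b2 = lose_one(b1, 3)
        turned = a + b2
        recycle = rng.random(n) < c
        oaa = np.where(recycle, turned, sample_fresh(n))

    a = sample_acetyl(n)
    b1 = lose_one(oaa, 4)
    b2 = lose_one(b1, 3)
    pyr = 3 * (rng.random(n) < q).astype(np.int64)
    lac = 3 * (rng.random(n) < q).astype(np.int64)
    akg = a + b1
    succ = a + b2  # same mass rule downstream to malate
    glut = np.where(rng.random(n) < cfg.glu_exchange, akg, 0)

    def mid(masses: np.ndarray, n_carbons: int, name: str) -> MIDProfile:
        counts = np.bincount(masses, minlength=n_carbons + 1).astype(float)
        return MIDProfile(name, counts / counts.sum())

    return {
        "pyruvate": mid(pyr, 3, "pyruvate"),
        "lactate": mid(lac, 3, "lactate"),
        "citrate": mid(a + oaa, 6, "citrate"),
        "alpha-ketoglutarate": mid(akg, 5, "alpha-ketoglutarate"),
        "succinate": mid(succ, 4, "succinate"),
        "fumarate": mid(succ, 4, "fumarate"),
        "malate": mid(succ, 4, "malate"),
        "aspartate": mid(oaa, 4, "aspartate"),
        "glutamate": mid(glut, 5, "glutamate"),
    }


def apply_natural_abundance(
    mid: MIDProfile,
    p13_natural: float,
    tracer_purity: float = 1.0,
    total_intensity: float = 1.0,
    protein_ug: float = 1.0,
) -> IsotopologSpectrum:
    """Forward-convolve a true MID into the spectrum an instrument would see.

    Uses the same binomial kernel as the correction matrix, so
    correct_natural_abundance(apply_natural_abundance(mid)) is the identity
    (up to solver tolerance). Intensities are scaled to ``total_intensity``.
    """
    C = correction_matrix(mid.n_carbons, p13_natural, tracer_purity)
    measured = C @ mid.fractions
    measured = measured / measured.sum() * float(total_intensity)
    return IsotopologSpectrum(mid.metabolite, mid.n_carbons, measured, protein_ug)


def first_turn_closed_form(cfg: LabelNetworkConfig) -> dict[str, float]:
    """Analytic citrate M+2 / M+3 fractions when no label recycles.

    Valid for ``cycling_weight == 0`` (any ``u_anaplerotic``): the OAA pool
    is exactly the fresh mixture, so citrate M+2 = q * phi_pdh * (1 - q_oaa)
    and citrate M+3 = (1 - q * phi_pdh) * q_oaa with q = f_glc_labeled *
    (1 - pyr_dilution) and q_oaa the fresh-OAA labeled probability.
    """
    if cfg.cycling_weight != 0:
        raise ValueError("closed form requires cycling_weight == 0")
    q_ac = cfg.q_acetyl
    q_oaa = cfg.q_fresh_oaa
    return {
        "citrate_m2": q_ac * (1.0 - q_oaa),
        "citrate_m3": (1.0 - q_ac) * q_oaa,
    }
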