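"""Seeded synthetic two-block NMR studies with known ground truth.

Six groups in a two-factor design (treatment x day): healthy controls C10 and
C14, adjuvant-only P10 and P14, and diseased N10 and N14.  Two biofluid-like
blocks share part of their metabolite library.  The effect map plants three
effect families:

* a peripheral-inflammation effect present in P10, N10 and N14 but vanished
  in P14 (which therefore reverts to the controls),
* a neurological effect present only in N10 and N14,
* a severity effect stronger in N14 than in N10.

Metabolites listed in ``exchange_metabolites`` additionally carry an
anti-correlated per-animal exchange term: for each such metabolite an
independent xi is drawn per animal and its concentration is multiplied by
exp(+xi) in block A and exp(-xi) in block B.  Either block alone therefore
sees a noisy group difference, while for metabolites present in both blocks
the exchange noise cancels when the blocks are combined — the motif that
makes mid-level fusion genuinely outperform single-block models.
``biological_sd_overrides`` lets individual metabolites (e.g. tightly
regulated glucose) deviate from the global biological variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .preprocess import SpectraBlock, Spectrum

__all__ = [
    "MetabolitePattern",
    "StudyConfig",
    "GroundTruth",
    "ConfigurationError",
    "simulate_spectrum",
    "simulate_study",
    "default_config",
    "GROUPS",
]

GROUPS = ("C10", "C14", "P10", "P14", "N10", "N14")
_LINESHAPES = ("lorentzian", "gaussian")


class ConfigurationError(ValueError):
    """A StudyConfig invariant is violated; the message names it."""


@dataclass
class MetabolitePattern:
    """A metabolite's spectral signature: a list of peaks plus a base level.

    Each peak is (center_ppm, width_ppm, relative_height, lineshape).  Width
    is the half-width at half-maximum for both lineshapes.
    """

    name: str
    peaks: list
    base_concentration: float

    def validate(self, ppm_range: tuple) -> None:
        lo, hi = ppm_range
        if self.base_concentration <= 0:
            raise ConfigurationError(
                f"metabolite {self.name}: base_concentration must be > 0"
            )
        if not self.peaks:
            raise ConfigurationError(f"metabolite {self.name}: needs >= 1 peak")
        for c, w, h, shape in self.peaks:
            if w <= 0:
                raise ConfigurationError(f"metabolite {self.name}: peak width <= 0")
            if h <= 0:
                raise ConfigurationError(f"metabolite {self.name}: peak height <= 0")
            if not (lo <= c <= hi):
                raise ConfigurationError(
                    f"metabolite {self.name}: peak center {c} outside ppm range"
                )
            if shape not in _LINESHAPES:
                raise ConfigurationError(
                    f"metabolite {self.name}: unknown lineshape {shape!r}"
                )

    def template(self, ppm: np.ndarray) -> np.ndarray:
        """Unit-concentration spectrum of this metabolite on a grid."""
        out = np.zeros_like(ppm, dtype=float)
        for c, w, h, shape in self.peaks:
            u = (ppm - c) / w
            if shape == "lorentzian":
                out += h / (1.0 + u * u)
            else:
                out += h * np.exp(-np.log(2.0) * u * u)
        return out


@dataclass
class StudyConfig:
    """Everything needed to draw one six-group, two-block study."""

    n_per_group: int = 14
    groups: tuple = GROUPS
    n_points: int = 2048
    ppm_range: tuple = (0.5, 9.0)
    metabolite_library: dict = field(default_factory=dict)  # block -> [patterns]
    effect_map: dict = field(default_factory=dict)  # metabolite -> group -> factor
    shift_jitter_sd: float = 0.004  # ppm
    baseline_amplitude: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    biological_sd: float = 0.15  # lognormal sigma on concentrations
    # per-metabolite overrides of biological_sd (e.g. tightly regulated
    # metabolites such as glucose vary much less between animals)
    biological_sd_overrides: dict = field(default_factory=dict)
    exchange_sd: float = 0.0  # anti-correlated between-block term
    exchange_metabolites: tuple = ()
    n10_heterogeneity: float = 0.0  # extra lognormal sigma on N10 effects

    # ------------------------------------------------------------------
    def block_ids(self) -> list:
        return list(self.metabolite_library.keys())

    def metabolite_names(self) -> list:
        names = []
        for pats in self.metabolite_library.values():
            for pat in pats:
                if pat.name not in names:
                    names.append(pat.name)
        return names

    def factor(self, metabolite: str, group: str) -> float:
        return float(self.effect_map.get(metabolite, {}).get(group, 1.0))

    def validate(self) -> None:
        if self.n_per_group < 4:
            raise ConfigurationError("n_per_group must be >= 4")
        lo, hi = self.ppm_range
        if not lo < hi:
            raise ConfigurationError("ppm_range low must be < high")
        if self.n_points < 8:
            raise ConfigurationError("n_points must be >= 8")
        if len(self.metabolite_library) != 2:
            raise ConfigurationError("exactly two blocks are required")
        if set(self.groups) != set(GROUPS):
            raise ConfigurationError(f"groups must be {set(GROUPS)}")
        for pats in self.metabolite_library.values():
            for pat in pats:
                pat.validate(self.ppm_range)
        names = set(self.metabolite_names())
        for m, per_group in self.effect_map.items():
            if m not in names:
                raise ConfigurationError(f"effect_map metabolite {m!r} not in library")
            for g, f in per_group.items():
                if g not in GROUPS:
                    raise ConfigurationError(f"effect_map group {g!r} unknown")
                if f <= 0:
                    raise ConfigurationError(
                        f"effect_map factor for {m}/{g} must be > 0"
                    )
        # topology invariants
        for m in self.effect_map:
            if self.factor(m, "P14") != self.factor(m, "C10"):
                raise ConfigurationError(
                    f"P14 must match control factors (violated by {m})"
                )
        def _differs(m, g):
            return self.factor(m, g) != self.factor(m, "C10")

        peripheral = [
            m
            for m in self.effect_map
            if all(_differs(m, g) for g in ("P10", "N10", "N14"))
        ]
        if not peripheral:
            raise ConfigurationError(
                "no peripheral effect: need a metabolite altered in P10, N10 and N14"
            )
        neuro = [
            m
            for m in self.effect_map
            if _differs(m, "N10") and _differs(m, "N14") and not _differs(m, "P10")
        ]
        if not neuro:
            raise ConfigurationError(
                "no neurological effect: need a metabolite altered in N10/N14 only"
            )
        severity = [
            m for m in self.effect_map if self.factor(m, "N14") > self.factor(m, "N10")
        ]
        if not severity:
            raise ConfigurationError(
                "no severity effect: need a metabolite with factor N14 > N10"
            )
        for m in self.exchange_metabolites:
            if m not in names:
                raise ConfigurationError(f"exchange metabolite {m!r} not in library")
        for m, sd in self.biological_sd_overrides.items():
            if m not in names:
                raise ConfigurationError(
                    f"biological_sd_overrides metabolite {m!r} not in library"
                )
            if sd < 0:
                raise ConfigurationError(
                    f"biological_sd_overrides for {m!r} must be >= 0"
                )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["metabolite_library"] = {
            b: [
                {
                    "name": p.name,
                    "peaks": [list(pk) for pk in p.peaks],
                    "base_concentration": p.base_concentration,
                }
                for p in pats
            ]
            for b, pats in self.metabolite_library.items()
        }
        d["groups"] = list(self.groups)
        d["ppm_range"] = list(self.ppm_range)
        d["exchange_metabolites"] = list(self.exchange_metabolites)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["metabolite_library"] = {
            b: [
                MetabolitePattern(
                    name=p["name"],
                    peaks=[tuple(pk) for pk in p["peaks"]],
                    base_concentration=float(p["base_concentration"]),
                )
                for p in pats
            ]
            for b, pats in d.get("metabolite_library", {}).items()
        }
        d["groups"] = tuple(d.get("groups", GROUPS))
        d["ppm_range"] = tuple(d.get("ppm_range", (0.5, 9.0)))
        d["exchange_metabolites"] = tuple(d.get("exchange_metabolites", ()))
        return cls(**d)

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def read_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What was planted: who discriminates what, and the realized nuisances."""

    contrasts: dict  # contrast -> block -> [(metabolite, direction)]
    concentrations: dict  # block -> DataFrame (samples x metabolites)
    jitter_coeffs: dict  # block -> DataFrame (samples x coefficients)
    baseline_coeffs: dict  # block -> DataFrame (samples x 4 cubic coefficients)
    discriminatory_ppm: dict  # block -> metabolite -> [peak centers]

    def to_json(self, path) -> None:
        payload = {
            "contrasts": self.contrasts,
            "concentrations": {
                b: df.to_dict(orient="index") for b, df in self.concentrations.items()
            },
            "jitter_coeffs": {
                b: df.to_dict(orient="index") for b, df in self.jitter_coeffs.items()
            },
            "baseline_coeffs": {
                b: df.to_dict(orient="index") for b, df in self.baseline_coeffs.items()
            },
            "discriminatory_ppm": self.discriminatory_ppm,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            contrasts=d["contrasts"],
            concentrations={
                b: pd.DataFrame.from_dict(v, orient="index")
                for b, v in d["concentrations"].items()
            },
            jitter_coeffs={
                b: pd.DataFrame.from_dict(v, orient="index")
                for b, v in d["jitter_coeffs"].items()
            },
            baseline_coeffs={
                b: pd.DataFrame.from_dict(v, orient="index")
                for b, v in d["baseline_coeffs"].items()
            },
            discriminatory_ppm=d["discriminatory_ppm"],
        )


# ----------------------------------------------------------------------
def simulate_spectrum(
    concentrations,
    library: list,
    jitter_coeffs,
    baseline,
    noise_sd: float,
    seed: int,
    ppm: np.ndarray,
    sample_id: str = "",
    block_id: str = "",
    group: str = "",
) -> Spectrum:
    """One spectrum: sum of concentration-weighted metabolite signatures.

    The ppm axis is warped per sample: signatures are evaluated at
    u = ppm - delta(ppm) with delta a polynomial in the centered, scaled
    coordinate, so a constant jitter coefficient d moves every peak by +d
    ppm.  ``baseline`` is an array on the grid or a callable of ppm.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size != len(library):
        raise ValueError(
            f"{concentrations.size} concentrations for {len(library)} metabolites"
        )
    ppm = np.asarray(ppm, dtype=float)
    jit = np.asarray(jitter_coeffs, dtype=float).ravel()
    mid = 0.5 * (ppm[0] + ppm[-1])
    span = max(abs(ppm[-1] - ppm[0]), 1e-12)
    u = (ppm - mid) / span
    delta = np.zeros_like(ppm)
    for k, a in enumerate(jit):
        delta += a * u**k
    warped = ppm - delta
    intensity = np.zeros_like(ppm)
    for c, pat in zip(concentrations, library):
        if c != 0.0:
            intensity += c * pat.template(warped)
    if callable(baseline):
        intensity += baseline(ppm)
    elif baseline is not None:
        intensity += np.asarray(baseline, dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity += rng.normal(0.0, noise_sd, size=ppm.size)
    return Spectrum(
        ppm=ppm, intensity=intensity, sample_id=sample_id, block_id=block_id,
        group=group,
    )


def _planted_contrasts(config: StudyConfig) -> tuple[dict, dict]:
    """Derive per-contrast discriminatory metabolites from the effect map."""
    pairs = [("C10", "P10"), ("P10", "N10"), ("N10", "N14"), ("C10", "N14")]
    contrasts: dict = {}
    for g1, g2 in pairs:
        name = f"{g1}_vs_{g2}"
        contrasts[name] = {}
        for block, pats in config.metabolite_library.items():
            entries = []
            for pat in pats:
                f1, f2 = config.factor(pat.name, g1), config.factor(pat.name, g2)
                if f1 != f2:
                    entries.append((pat.name, "up" if f2 > f1 else "down"))
            contrasts[name][block] = entries
    ppm_map: dict = {}
    for block, pats in config.metabolite_library.items():
        ppm_map[block] = {}
        for pat in pats:
            if any(
                config.factor(pat.name, g) != config.factor(pat.name, "C10")
                for g in GROUPS
            ):
                ppm_map[block][pat.name] = [float(pk[0]) for pk in pat.peaks]
    return contrasts, ppm_map


def simulate_study(config: StudyConfig):
    """Draw a full study: two SpectraBlocks plus the GroundTruth record.

    Animals are shared between blocks: per-animal systemic (lognormal)
    concentration deviations are common to both blocks, while the exchange
    term enters the two blocks with opposite sign.  Identical config and
    seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    blocks = config.block_ids()
    ppm = {
        b: np.linspace(config.ppm_range[0], config.ppm_range[1], config.n_points)
        for b in blocks
    }
    lib = config.metabolite_library
    met_names = config.metabolite_names()

    sample_ids, sample_groups = [], []
    for g in config.groups:
        for i in range(config.n_per_group):
            sample_ids.append(f"{g}-{i + 1:02d}")
            sample_groups.append(g)
    n = len(sample_ids)

    conc = {b: np.zeros((n, len(lib[b]))) for b in blocks}
    jit = {b: np.zeros((n, 3)) for b in blocks}
    base = {b: np.zeros((n, 4)) for b in blocks}
    intens = {b: np.zeros((n, config.n_points)) for b in blocks}

    for s, (sid, g) in enumerate(zip(sample_ids, sample_groups)):
        # systemic per-animal deviation, shared across blocks
        z = {
            m: rng.normal(
                0.0, config.biological_sd_overrides.get(m, config.biological_sd)
            )
            for m in met_names
        }
        # per-metabolite blood<->CSF exchange imbalance: +xi in the first
        # block, -xi in the second, independent across metabolites
        xi = {
            m: (rng.normal(0.0, config.exchange_sd) if config.exchange_sd > 0 else 0.0)
            for m in config.exchange_metabolites
        }
        het = (
            {m: rng.normal(0.0, config.n10_heterogeneity) for m in met_names}
            if (config.n10_heterogeneity > 0 and g == "N10")
            else None
        )
        for b in blocks:
            sign = 1.0 if b == blocks[0] else -1.0
            row = np.empty(len(lib[b]))
            for k, pat in enumerate(lib[b]):
                f = config.factor(pat.name, g)
                logc = np.log(pat.base_concentration * f) + z[pat.name]
                if het is not None and f != _control_factor(config, pat.name):
                    logc += het[pat.name]
                if pat.name in config.exchange_metabolites:
                    logc += sign * xi[pat.name]
                row[k] = np.exp(logc)
            conc[b][s] = row
            jc = rng.normal(0.0, config.shift_jitter_sd, size=3)
            jit[b][s] = jc
            bc = rng.normal(0.0, 1.0, size=4)
            base[b][s] = bc
            mid = 0.5 * (ppm[b][0] + ppm[b][-1])
            span = ppm[b][-1] - ppm[b][0]
            u = (ppm[b] - mid) / span
            baseline = bc[0] + bc[1] * u + bc[2] * u**2 + bc[3] * u**3
            mx = np.abs(baseline).max()
            if config.baseline_amplitude > 0 and mx > 0:
                baseline = baseline * (config.baseline_amplitude / mx)
                # keep it non-negative so total areas stay positive
                baseline = baseline - baseline.min()
            else:
                baseline = np.zeros_like(u)
            noise_seed = int(rng.integers(0, 2**63 - 1))
            spec = simulate_spectrum(
                row,
                lib[b],
                jc,
                baseline,
                config.noise_sd,
                noise_seed,
                ppm[b],
                sample_id=sid,
                block_id=b,
                group=g,
            )
            intens[b][s] = spec.intensity

    metadata = pd.DataFrame(
        {"group": sample_groups}, index=pd.Index(sample_ids, name="sample_id")
    )
    out_blocks = [
        SpectraBlock(
            ppm=ppm[b], intensities=intens[b], metadata=metadata.copy(), block_id=b
        )
        for b in blocks
    ]
    contrasts, ppm_map = _planted_contrasts(config)
    gt = GroundTruth(
        contrasts=contrasts,
        concentrations={
            b: pd.DataFrame(
                conc[b], index=sample_ids, columns=[p.name for p in lib[b]]
            )
            for b in blocks
        },
        jitter_coeffs={
            b: pd.DataFrame(jit[b], index=sample_ids, columns=["a0", "a1", "a2"])
            for b in blocks
        },
        baseline_coeffs={
            b: pd.DataFrame(
                base[b], index=sample_ids, columns=["b0", "b1", "b2", "b3"]
            )
            for b in blocks
        },
        discriminatory_ppm=ppm_map,
    )
    return out_blocks[0], out_blocks[1], gt


def _control_factor(config: StudyConfig, metabolite: str) -> float:
    return config.factor(metabolite, "C10")


# ----------------------------------------------------------------------
def default_config(seed: int = 0, n_per_group: int = 14) -> StudyConfig:
    """The frozen default six-group study.

    The effect map plants three orthogonal contrasts:

    * peripheral (any treatment vs control): lactate and tyrosine, strongly
      altered in P10/N10/N14 and back to control levels in P14;
    * neurological (disease vs adjuvant-alone): glutamine, myo-inositol,
      valine and acetate move in N10/N14 relative to P10;
    * severity (day 14 vs day 10 disease): creatine, citrate and alanine
      differ between N14 and N10.

    Most discriminatory metabolites also carry a per-metabolite
    anti-correlated "exchange" term between the two fluids, so a single-fluid
    model sees substantially noisier contrasts than the fused model, in which
    the exchange noise of shared metabolites cancels.  Formate (blockA) and
    glutamate (blockB) are raised in P10 only; their factors are chosen so
    the P10 vs N10 total-area swing of each block is ~zero, and the severity
    family is internally area-balanced, so total-area normalization does not
    itself encode the group structure.  Glucose, the dominant inert peak, is
    tightly regulated (small biological variance), giving the total-area
    normalization a stable reference.
    """
    L, G = "lorentzian", "gaussian"
    lib_a = [
        MetabolitePattern("glucose", [(3.40, 0.015, 1.0, L), (3.80, 0.015, 0.8, L)], 8.0),
        MetabolitePattern("lactate", [(1.33, 0.012, 1.0, L), (4.11, 0.012, 0.35, L)], 2.0),
        MetabolitePattern("glutamine", [(2.45, 0.014, 1.0, L)], 0.9),
        MetabolitePattern("acetate", [(1.92, 0.012, 1.0, L)], 2.0),
        MetabolitePattern("creatine", [(3.03, 0.012, 1.0, L)], 2.5),
        MetabolitePattern("citrate", [(2.55, 0.013, 1.0, L), (2.66, 0.013, 0.9, L)], 1.3),
        MetabolitePattern("formate", [(8.45, 0.012, 0.6, G)], 1.5),
        MetabolitePattern("myo_inositol", [(4.06, 0.014, 0.5, L)], 2.0),
    ]
    lib_b = [
        MetabolitePattern("glucose", [(3.40, 0.015, 1.0, L), (3.80, 0.015, 0.8, L)], 10.0),
        MetabolitePattern("lactate", [(1.33, 0.012, 1.0, L), (4.11, 0.012, 0.35, L)], 2.5),
        MetabolitePattern("glutamine", [(2.45, 0.014, 1.0, L)], 1.4),
        MetabolitePattern("tyrosine", [(6.90, 0.014, 0.8, L), (7.19, 0.014, 0.8, L)], 1.0),
        MetabolitePattern("glutamate", [(2.35, 0.013, 1.0, L)], 2.5),
        MetabolitePattern("creatine", [(3.03, 0.012, 1.0, L)], 2.5),
        MetabolitePattern("valine", [(0.99, 0.011, 0.7, L), (1.04, 0.011, 0.7, L)], 2.0),
        MetabolitePattern("alanine", [(1.48, 0.012, 0.9, L)], 2.5),
    ]
    effect_map = {
        # peripheral: altered in P10, N10, N14; P14 back to control
        "lactate": {"P10": 2.0, "N10": 2.0, "N14": 2.0},
        "tyrosine": {"P10": 0.50, "N10": 0.50, "N14": 0.50},
        # neurological: opposite movement in adjuvant-alone vs disease
        "glutamine": {"P10": 0.66, "N10": 1.52, "N14": 1.52},
        "myo_inositol": {"P10": 1.25, "N10": 0.74, "N14": 0.74},
        "valine": {"P10": 1.28, "N10": 0.86, "N14": 0.86},
        "acetate": {"N10": 1.12, "N14": 1.12},
        # severity: N14 beyond N10, raises balanced by drops so the
        # N14 vs N10 total-area swing per block is ~zero
        "creatine": {"N10": 0.78, "N14": 1.50},
        "citrate": {"N10": 1.30, "N14": 0.62},
        "alanine": {"N10": 1.14, "N14": 0.48},
        # P10-only balancers: factors solved so the P10 vs N10 total-area
        # swing of each block is ~zero
        "formate": {"P10": 2.2},
        "glutamate": {"P10": 1.039},
    }
    return StudyConfig(
        n_per_group=n_per_group,
        n_points=2048,
        ppm_range=(0.5, 9.0),
        metabolite_library={"blockA": lib_a, "blockB": lib_b},
        effect_map=effect_map,
        shift_jitter_sd=0.004,
        baseline_amplitude=0.5,
        noise_sd=0.01,
        seed=seed,
        biological_sd=0.12,
        biological_sd_overrides={"glucose": 0.04},
        exchange_sd=0.40,
        exchange_metabolites=(
            "glutamine",
            "myo_inositol",
            "valine",
            "formate",
            "glutamate",
            "creatine",
            "citrate",
            "alanine",
        ),
    )
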