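"""Synthetic multiplexed-DIA report generator with known ground truth.

The generator emulates the long-report dialect consumed by
:mod:`mdiaquant.report_io` for the evaluation designs used to characterize
reference-channel quantification: fixed single-cell-equivalent targets
(scBenchmark), graded target amounts (scQuant), deliberately empty target
channels (scDecoy), graded reference amounts (scReference), and the bulk
mixing designs (three-plex 17:2:1, five-plex 1:2:4:2:1, mixed species).

Intensity model, per ion (fragment or MS1) and per run x channel:

    I = A_p * w_f * (amount / 250 pg) * exp(N(0, sigma_ion))   [+ background]

where ``A_p`` is a log-normal protein abundance spanning roughly four
orders of magnitude over +/-2 sigma, ``w_f`` a per-fragment relative
response, and the channel factor expresses the loaded amount in
single-cell equivalents (250 pg). The per-ion noise combines a constant
multiplicative CV with a Poisson-style shot-noise component whose CV is
sqrt(shot_noise_scale / I), shot_noise_scale being the intensity of one
elementary ion count: faint ions are relatively noisier — the mechanism
by which a high-abundance reference channel stabilizes ratio estimates.
Dropout is governed separately by the peak-picking threshold
detection_lambda, with detection probability 1 - exp(-I / lambda),
giving abundance-dependent missingness (the shot-noise completeness
model 1 - exp(-x)). A configurable fraction
of ions is contaminated with additive exponential background. The
background scale is ``background_scale`` times the median
single-cell-equivalent ion intensity at a 10 ng total run load, and
scales proportionally with the total material loaded in the run
(chemical noise comes from coeluting peptides of the whole sample);
with the default multiple of 5 the interference dominates a contaminated
single-cell target ion under a 10 ng reference, reproducing the
asymmetric ratio distributions that motivate lower-quantile ratio
trimming. Channel q-values are a
deliberate caricature sufficient to exercise the filtering and
count-based-FDR plumbing: true-signal rows draw from U(0, 0.01), rows that
exist only through background from U(0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chemistry import LabelScheme, label_count, five_plex_lysn, three_plex_trypsin
from .report_io import ExperimentDesign, write_design, write_report

#: one single-cell equivalent of peptide input, in pg
SINGLE_CELL_PG = 250.0

_AA_NO_KR = list("ADEFGHILMNPQSTVWY")


@dataclass(frozen=True)
class ChannelSpec:
    channel: int
    role: str        # reference | target | empty
    amount_pg: float

    def __post_init__(self):
        if self.role == "empty" and self.amount_pg != 0:
            raise ValueError(f"empty channel {self.channel} must have amount 0")
        if self.role != "empty" and self.amount_pg <= 0:
            raise ValueError(f"{self.role} channel {self.channel} needs a positive amount")


@dataclass(frozen=True)
class RunSpec:
    run_id: str
    channels: tuple[ChannelSpec, ...]


@dataclass(frozen=True)
class SimulationConfig:
    runs: tuple[RunSpec, ...]
    scheme: LabelScheme = field(default_factory=three_plex_trypsin)
    n_proteins: int = 100
    precursors_per_protein: tuple[int, int] = (3, 8)
    fragments_per_precursor: tuple[int, int] = (6, 13)
    abundance_median: float = 100.0
    abundance_sigma_log10: float = 1.0
    noise_cv: float = 0.25
    interference_fraction: float = 0.10
    background_scale: float = 5.0
    detection_lambda: float = 20.0
    #: intensity of one elementary ion count; shot-noise CV^2 = scale / I.
    #: 0 disables the shot component. Decoupled from detection_lambda: dropout
    #: is governed by the peak-picking threshold, shot noise by ion counting.
    shot_noise_scale: float = 5.0
    #: load-independent MS1 chemical-noise floor, in units of the median
    #: single-cell ion intensity. MS1 spectra are unfiltered by isolation or
    #: ion mobility, so every MS1 area sits on chemical background; fragment
    #: (MS2) ions only see the per-ion interference above. 0 disables.
    ms1_background_floor: float = 1.0
    ms1_response: float = 2.0
    seed: int = 0
    #: optional mixed-species design: species -> fraction of proteins
    species_fractions: dict[str, float] | None = None
    #: species -> channel -> extra abundance factor
    species_channel_factors: dict[str, dict[int, float]] | None = None

    def __post_init__(self):
        if not self.runs:
            raise ValueError("config needs at least one run")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        for lo, hi in (self.precursors_per_protein, self.fragments_per_precursor):
            if not 1 <= lo <= hi:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")
        if self.noise_cv < 0 or not 0 <= self.interference_fraction <= 1:
            raise ValueError("invalid noise parameters")
        if self.detection_lambda < 0:
            raise ValueError("detection_lambda must be non-negative")
        for run in self.runs:
            for spec in run.channels:
                if spec.channel not in self.scheme.channels:
                    raise ValueError(
                        f"channel {spec.channel} not in scheme {self.scheme.name}"
                    )
        if (self.species_fractions is None) != (self.species_channel_factors is None):
            raise ValueError("species fractions and channel factors go together")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def design(self) -> ExperimentDesign:
        rows = [
            {
                "run": run.run_id,
                "channel": spec.channel,
                "role": spec.role,
                "sample_name": f"{run.run_id}_d{spec.channel}",
            }
            for run in self.runs
            for spec in run.channels
        ]
        return ExperimentDesign(pd.DataFrame(rows))


@dataclass
class GroundTruth:
    """Everything needed for parameter-recovery tests."""

    protein_abundance: pd.Series           # protein -> A_p
    precursors: pd.DataFrame               # precursor, protein, species, n_fragments, base_total
    channel_amounts: pd.DataFrame          # run, channel, role, amount_pg
    observations: pd.DataFrame             # per (precursor, run, channel): truth + contamination

    def true_channel_ratio(self, run_id: str, channel_a: int, channel_b: int) -> float:
        """Configured abundance ratio channel_a / channel_b within one run."""
        amounts = self.channel_amounts.set_index(["run", "channel"])["amount_pg"]
        return float(amounts[(run_id, channel_a)] / amounts[(run_id, channel_b)])


@dataclass
class SimulationResult:
    report: pd.DataFrame
    design: ExperimentDesign
    ground_truth: GroundTruth
    config: SimulationConfig


def _peptide(rng: np.random.Generator, protease: str) -> str:
    body = "".join(rng.choice(_AA_NO_KR, size=int(rng.integers(6, 13))))
    if protease == "Lys-N":
        return "K" + body
    return body + ("K" if rng.random() < 0.5 else "R")


def _decorate(seq: str, charge: int, channel: int, protease: str) -> str:
    """Channel-decorated modified sequence + charge, mirroring the dialect
    parsed by :func:`mdiaquant.report_io.parse_channel`."""
    out = f"(Dimethyl-n-{channel})" + seq.replace("K", f"K(Dimethyl-K-{channel})")
    return f"{out}{charge}"


def simulate_report(cfg: SimulationConfig) -> SimulationResult:
    """Generate a report, its design table and the generating ground truth.

    Deterministic: identical config and seed give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
    # median single-cell-equivalent ion intensity (analytic, for background scale)
    median_sc_ion = cfg.abundance_median * math.exp(-0.5)
    # chemical background tracks the total material in a run; the documented
    # background_scale applies at a 10 ng total load
    reference_load_pg = 10_000.0

    # species assignment
    if cfg.species_fractions:
        species_names = sorted(cfg.species_fractions)
        probs = np.array([cfg.species_fractions[s] for s in species_names], dtype=float)
        probs = probs / probs.sum()
    else:
        species_names, probs = ["single"], np.array([1.0])

    protease = cfg.scheme.protease
    proteins = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    abundance = cfg.abundance_median * np.power(
        10.0, rng.normal(0.0, cfg.abundance_sigma_log10, size=cfg.n_proteins)
    )
    species = [species_names[i] for i in rng.choice(len(species_names), size=cfg.n_proteins, p=probs)]

    precursor_rows = []
    frag_weights: dict[str, np.ndarray] = {}
    meta: dict[str, tuple[str, str, float, str, int]] = {}
    lo_p, hi_p = cfg.precursors_per_protein
    lo_f, hi_f = cfg.fragments_per_precursor
    for p_idx, protein in enumerate(proteins):
        for _ in range(int(rng.integers(lo_p, hi_p + 1))):
            seq = _peptide(rng, protease)
            charge = int(rng.integers(2, 4))
            prec = f"{seq}_{charge}"
            if prec in frag_weights:
                continue
            n_frag = int(rng.integers(lo_f, hi_f + 1))
            w = rng.lognormal(mean=-0.5, sigma=0.8, size=n_frag)
            frag_weights[prec] = w
            a = float(abundance[p_idx])
            meta[prec] = (protein, seq, a, species[p_idx], charge)
            precursor_rows.append(
                {
                    "precursor": prec,
                    "protein": protein,
                    "species": species[p_idx],
                    "n_fragments": n_frag,
                    "base_total": a * (w.sum() + cfg.ms1_response),
                }
            )

    channel_amount_rows = [
        {"run": run.run_id, "channel": spec.channel, "role": spec.role,
         "amount_pg": spec.amount_pg}
        for run in cfg.runs for spec in run.channels
    ]

    report_records = []
    obs_records = []
    for run in cfg.runs:
        total_load = sum(spec.amount_pg for spec in run.channels)
        background_run = (
            cfg.background_scale * median_sc_ion * total_load / reference_load_pg
        )
        for spec in run.channels:
            base_factor = spec.amount_pg / SINGLE_CELL_PG
            for prec, w in frag_weights.items():
                protein, seq, a, sp, charge = meta[prec]
                factor = base_factor
                if cfg.species_channel_factors and sp in cfg.species_channel_factors:
                    factor *= cfg.species_channel_factors[sp].get(spec.channel, 1.0)
                n_ion = len(w) + 1  # fragments + MS1
                base = np.concatenate([a * w * factor, [a * cfg.ms1_response * factor]])
                # per-ion sigma: constant multiplicative CV plus shot noise
                # with CV^2 = lambda / I (median-unbiased log-normal draw)
                sigma_ion = np.full(n_ion, sigma)
                if cfg.shot_noise_scale > 0:
                    with np.errstate(divide="ignore"):
                        shot_cv2 = np.where(base > 0, cfg.shot_noise_scale / base, 0.0)
                    sigma_ion = np.sqrt(sigma**2 + np.log1p(shot_cv2))
                if (sigma_ion > 0).any():
                    noise = np.exp(rng.normal(0.0, 1.0, size=n_ion) * sigma_ion)
                else:
                    noise = np.ones(n_ion)
                intensity = base * noise
                contaminated = rng.random(n_ion) < cfg.interference_fraction
                background_added = np.zeros(n_ion)
                if contaminated.any() and background_run > 0:
                    background_added = np.where(
                        contaminated, rng.exponential(background_run, size=n_ion), 0.0
                    )
                # MS1 background sits under the integrated envelope of a real
                # peak; a channel loaded with nothing has no envelope to
                # integrate, so empty channels only gain signal via the
                # per-ion interference events above.
                if cfg.ms1_background_floor > 0 and spec.amount_pg > 0:
                    background_added[-1] += rng.exponential(
                        cfg.ms1_background_floor * median_sc_ion
                    )
                intensity = intensity + background_added
                # Dropout follows the underlying ion flux (expected signal
                # plus any real interference), not the recorded area, so the
                # missingness law is exactly 1 - exp(-x / lambda) without
                # conditional-on-detection truncation bias. Base-driven and
                # background-driven detections are drawn separately: their
                # union reproduces 1 - exp(-(base+bg)/lambda), and rows whose
                # every detected ion is background-only are the false channel
                # assignments that Channel.Q filtering exists to remove.
                if cfg.detection_lambda > 0:
                    detected_base = rng.random(n_ion) < 1.0 - np.exp(
                        -base / cfg.detection_lambda
                    )
                    detected_bg = rng.random(n_ion) < 1.0 - np.exp(
                        -background_added / cfg.detection_lambda
                    )
                    detected = detected_base | detected_bg
                else:
                    detected_base = intensity > 0
                    detected = detected_base
                obs_records.append(
                    {
                        "precursor": prec,
                        "run": run.run_id,
                        "channel": spec.channel,
                        "true_total": float(base.sum()),
                        "n_ions": n_ion,
                        "n_detected": int(detected.sum()),
                        "n_contaminated": int(contaminated.sum()),
                    }
                )
                if not detected.any():
                    continue
                frags = np.where(detected[:-1], intensity[:-1], np.nan)
                ms1 = float(intensity[-1]) if detected[-1] else math.nan
                translated = float(np.nansum(frags)) if np.isfinite(frags).any() else math.nan
                pure_signal = bool(spec.amount_pg > 0 and detected_base.any())
                report_records.append(
                    {
                        "run_id": run.run_id,
                        "protein_group": protein,
                        "genes": protein,
                        "precursor_id": _decorate(seq, charge, spec.channel, protease),
                        "modified_sequence": _decorate(seq, charge, spec.channel, protease)[:-1],
                        "stripped_sequence": seq,
                        "charge": charge,
                        "channel": spec.channel,
                        "q_value": float(rng.uniform(0, 0.009)),
                        "global_pg_q_value": float(rng.uniform(0, 0.009)),
                        "pg_q_value": float(rng.uniform(0, 0.04)),
                        "lib_pg_q_value": float(rng.uniform(0, 0.009)),
                        "channel_q_value": float(
                            rng.uniform(0, 0.01) if pure_signal else rng.uniform(0, 1)
                        ),
                        "translated_q_value": float(rng.uniform(0, 0.009)),
                        "ms1_area": ms1,
                        "precursor_translated": translated,
                        "precursor_normalised": translated,
                        "fragment_quant_raw": list(frags),
                    }
                )

    report = pd.DataFrame(report_records)
    truth = GroundTruth(
        protein_abundance=pd.Series(abundance, index=proteins, name="abundance"),
        precursors=pd.DataFrame(precursor_rows),
        channel_amounts=pd.DataFrame(channel_amount_rows),
        observations=pd.DataFrame(obs_records),
    )
    return SimulationResult(report=report, design=cfg.design(),
                            ground_truth=truth, config=cfg)


def write_simulation(result: SimulationResult, outdir) -> dict[str, str]:
    """Write report.tsv, design.tsv and ground_truth.tsv under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": str(outdir / "report.tsv"),
        "design": str(outdir / "design.tsv"),
        "ground_truth": str(outdir / "ground_truth.tsv"),
    }
    write_report(result.report, paths["report"])
    write_design(result.design, paths["design"])
    truth = result.ground_truth
    merged = truth.observations.merge(
        truth.precursors[["precursor", "protein", "species", "base_total"]],
        on="precursor",
    ).merge(truth.channel_amounts, on=["run", "channel"])
    merged.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths


# --- presets ----------------------------------------------------------------


def _sc_run(run_id: str, ref: float, t4: float, t8: float) -> RunSpec:
    def role(amount):
        return "empty" if amount == 0 else "target"

    return RunSpec(run_id, (
        ChannelSpec(0, "reference", ref),
        ChannelSpec(4, role(t4), t4),
        ChannelSpec(8, role(t8), t8),
    ))


def _preset_scbenchmark(seed: int) -> SimulationConfig:
    # 10 ng reference, 250 pg (one single-cell equivalent) in both targets
    runs = tuple(_sc_run(f"run{i+1}", 10_000.0, 250.0, 250.0) for i in range(4))
    return SimulationConfig(runs=runs, n_proteins=120, seed=seed)


def _preset_scquant(seed: int) -> SimulationConfig:
    # graded target amounts 62.5-2000 pg around one single-cell equivalent
    runs = (
        _sc_run("run1", 10_000.0, 62.5, 250.0),
        _sc_run("run2", 10_000.0, 250.0, 1000.0),
        _sc_run("run3", 10_000.0, 1000.0, 2000.0),
        _sc_run("run4", 10_000.0, 250.0, 250.0),
    )
    return SimulationConfig(runs=runs, n_proteins=120, seed=seed)


def _preset_scdecoy(seed: int) -> SimulationConfig:
    # four empty target channels vs four filled ones, same reference
    runs = (
        _sc_run("run1", 10_000.0, 0.0, 0.0),
        _sc_run("run2", 10_000.0, 0.0, 0.0),
        _sc_run("run3", 10_000.0, 250.0, 250.0),
        _sc_run("run4", 10_000.0, 250.0, 250.0),
    )
    return SimulationConfig(runs=runs, n_proteins=120, seed=seed)


def _preset_screference(seed: int) -> SimulationConfig:
    # reference amount graded over 40x, single-cell equivalents in targets
    amounts = (250.0, 1000.0, 2500.0, 5000.0, 10_000.0)
    runs = tuple(
        _sc_run(f"ref{int(a)}", a, 250.0, 250.0) for a in amounts
    )
    return SimulationConfig(runs=runs, n_proteins=120, seed=seed)


def _preset_bsa(seed: int) -> SimulationConfig:
    # three-plex bulk mixing 17:2:1 (d0:d4:d8); clean multiplicative noise
    runs = tuple(
        RunSpec(f"rep{i+1}", (
            ChannelSpec(0, "reference", 17 * 250.0),
            ChannelSpec(4, "target", 2 * 250.0),
            ChannelSpec(8, "target", 1 * 250.0),
        ))
        for i in range(3)
    )
    return SimulationConfig(
        runs=runs, n_proteins=100, precursors_per_protein=(4, 8),
        noise_cv=0.10, interference_fraction=0.0, seed=seed,
    )


def _preset_fiveplex(seed: int) -> SimulationConfig:
    # five-plex Lys-N bulk accuracy design 1:2:4:2:1 (d0:d2:d4:d6:d8)
    base = 5_000.0
    ratios = {0: 1, 2: 2, 4: 4, 6: 2, 8: 1}
    runs = tuple(
        RunSpec(f"rep{i+1}", tuple(
            ChannelSpec(ch, "reference" if ch == 0 else "target", base * r)
            for ch, r in ratios.items()
        ))
        for i in range(3)
    )
    return SimulationConfig(
        runs=runs, scheme=five_plex_lysn(), n_proteins=320,
        precursors_per_protein=(3, 6), noise_cv=0.10,
        interference_fraction=0.05, seed=seed,
    )


def _preset_mixed_species(seed: int) -> SimulationConfig:
    # equal total loads; opposing species gradients, human as the 1:1:1 anchor
    runs = tuple(
        RunSpec(f"rep{i+1}", (
            ChannelSpec(0, "reference", 50_000.0),
            ChannelSpec(4, "target", 50_000.0),
            ChannelSpec(8, "target", 50_000.0),
        ))
        for i in range(3)
    )
    return SimulationConfig(
        runs=runs, n_proteins=200, noise_cv=0.10, interference_fraction=0.05,
        species_fractions={"human": 0.6, "yeast": 0.25, "ecoli": 0.15},
        species_channel_factors={
            "human": {0: 1.0, 4: 1.0, 8: 1.0},
            "yeast": {0: 2.0, 4: 1.0, 8: 0.5},
            "ecoli": {0: 0.25, 4: 1.0, 8: 4.0},
        },
        seed=seed,
    )


_PRESETS = {
    "scBenchmark": _preset_scbenchmark,
    "scQuant": _preset_scquant,
    "scDecoy": _preset_scdecoy,
    "scReference": _preset_screference,
    "bsa17_2_1": _preset_bsa,
    "fiveplex_1_2_4_2_1": _preset_fiveplex,
    "mixed_species": _preset_mixed_species,
}


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Named evaluation design with documented channel amounts."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return factory(seed)


PRESET_NAMES = tuple(sorted(_PRESETS))
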