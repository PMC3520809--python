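"""Synthetic longitudinal cohort generator.

Replaces the study's rats with a simulated cohort carrying the statistical
structure the downstream analysis assumes:

* per-animal latent injury severity (log-normal, mean 1) that jointly shifts
  collagen accrual, the CC-IBS dose trajectory, MCV decline and LVESD growth,
  inducing a positive coupling between an animal's CC-IBS dose-slope and its
  terminal collagen content;
* group means and spreads per dose taken from the study's published group
  statistics, with dose-dependent attrition reproducing the examined-N row
  (60/23/21/14/9/7) and the histology sacrifice schedule (6/8/6/10 hearts);
* raw measurement fixtures per exam: IBS intensity traces with a matched
  rubber-phantom reference, per-cycle M-mode dimensions, and stained-section
  field images for sacrificed hearts.

Injury-to-measurement coupling is centered within each realized dose group,
so that configured group means are recovered exactly at zero noise
regardless of attrition; the residual spread is shrunk so the total
group spread matches the configured one.

Attrition bookkeeping: spontaneous deaths remove the highest-injury animals
first; sacrifices are drawn at random among animals alive at the scheduled
dose (sacrifice was scheduled, not injury-informed). Exam cohorts are
non-nested: an animal alive at a dose need not be examined at it, which is
what reconciles the examined-N row with the sacrifice counts (e.g. ten
hearts at 16 mg/kg versus seven exams).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import EXAM_VARIABLES, GeneratorConfig
from .echo import MModeMeasurement
from .errors import ConfigurationError, InputError, SamplingError
from .histology import HistologyField
from .utc import IBSTrace


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from a single seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


@dataclass
class AnimalState:
    """Latent state and fate of one animal."""

    animal_id: int
    latent_injury: float
    alive_through_dose: float
    sacrificed_at: Optional[float] = None
    true_collagen_pct: Optional[float] = None
    exam_doses: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.latent_injury < 0:
            raise InputError("latent injury must be non-negative")
        if self.sacrificed_at is not None and self.sacrificed_at > self.alive_through_dose:
            raise InputError("sacrifice dose cannot exceed the dose survived through")


@dataclass
class Cohort:
    """Generated cohort: animal states plus per-dose measurement records."""

    config: GeneratorConfig
    seed: int
    animals: List[AnimalState]
    #: one row per exam: animal_id, dose_mg_per_kg, cc_ibs, mcv, sf_pct,
    #: lvedd_cm, lvesd_cm, hr_bpm (drawn target values, pre-measurement)
    exams: pd.DataFrame
    #: one row per sacrificed heart: animal_id, dose_mg_per_kg, true_collagen_pct
    hearts: pd.DataFrame

    def animal(self, animal_id: int) -> AnimalState:
        return next(a for a in self.animals if a.animal_id == animal_id)

    def group_sizes(self) -> List[int]:
        return [
            int((self.exams["dose_mg_per_kg"] == d).sum())
            for d in self.config.dose_schedule
        ]


# ---------------------------------------------------------------------------
# attrition planning


def _alive_requirements(config: GeneratorConfig) -> List[int]:
    """Minimum number of dosed animals that must be alive at each DXR dose.

    Backward recursion over the post-baseline schedule:
    ``R_j = max(N_j, sacrifices_j + R_{j+1})``.
    """
    doses = config.dose_schedule[1:]
    sizes = config.group_sizes[1:]
    req = [0] * (len(doses) + 1)
    for j in range(len(doses) - 1, -1, -1):
        s_j = config.sacrifice_schedule.get(doses[j], 0)
        req[j] = max(sizes[j], s_j + req[j + 1])
    return req


def _plan_fates(
    config: GeneratorConfig, injuries: np.ndarray, rng: np.random.Generator
) -> Tuple[List[AnimalState], Dict[float, List[int]]]:
    """Assign controls, sacrifices, deaths and per-dose exam sets.

    Returns the animal states and a map dose -> examined animal ids.
    """
    n = config.n_baseline
    doses = config.dose_schedule
    base = doses[0]
    ids = np.arange(1, n + 1)

    n_controls = config.sacrifice_schedule.get(base, 0)
    req = _alive_requirements(config)
    if n - n_controls < req[0] and len(doses) > 1:
        raise ConfigurationError(
            f"{n} baseline animals minus {n_controls} controls cannot sustain "
            f"the examined-N row and sacrifice schedule (need {req[0]})"
        )

    control_ids = sorted(rng.choice(ids, size=n_controls, replace=False).tolist())
    states = {
        i: AnimalState(animal_id=int(i), latent_injury=float(s), alive_through_dose=base)
        for i, s in zip(ids, injuries)
    }
    for i in control_ids:
        states[i].sacrificed_at = base

    exam_sets: Dict[float, List[int]] = {base: ids.tolist()}
    for i in ids:
        states[i].exam_doses.append(base)

    alive = sorted(set(ids.tolist()) - set(control_ids))

    def kill_highest_injury(pool: List[int], k: int, last_dose: float) -> List[int]:
        by_injury = sorted(pool, key=lambda i: (-states[i].latent_injury, i))
        dead = by_injury[:k]
        for i in dead:
            states[i].alive_through_dose = last_dose
        return sorted(set(pool) - set(dead))

    # deaths between baseline and the first DXR exam
    if len(doses) > 1:
        alive = kill_highest_injury(alive, len(alive) - req[0], base)

    for j, dose in enumerate(doses[1:]):
        for i in alive:
            states[i].alive_through_dose = dose
        n_exam = config.group_sizes[j + 1]
        n_sac = config.sacrifice_schedule.get(dose, 0)
        sac = sorted(rng.choice(alive, size=n_sac, replace=False).tolist())
        if n_sac >= n_exam:
            examined = sorted(rng.choice(sac, size=n_exam, replace=False).tolist())
        else:
            rest = sorted(set(alive) - set(sac))
            fill = sorted(rng.choice(rest, size=n_exam - n_sac, replace=False).tolist())
            examined = sorted(sac + fill)
        exam_sets[dose] = examined
        for i in examined:
            states[i].exam_doses.append(dose)
        for i in sac:
            states[i].sacrificed_at = dose
        alive = sorted(set(alive) - set(sac))
        if j + 1 < len(doses) - 1:
            alive = kill_highest_injury(alive, len(alive) - req[j + 1], dose)
    # animals still alive after the last dose completed the protocol

    return list(states.values()), exam_sets


# ---------------------------------------------------------------------------
# value drawing


def _draw_group(
    config: GeneratorConfig,
    var: str,
    dose: float,
    injuries: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one variable for all members of a realized dose group.

    ``value = baseline_mean + effect * h_i + residual noise`` with the
    positive per-animal gain ``h_i = s_i**(coupling*weight)`` normalized to
    group mean 1. A positive gain keeps every animal's expected trajectory
    direction-consistent with the group dose effect (a zero-injury animal
    has a flat trajectory); the normalization recovers configured group
    means exactly at zero noise, and the residual SD is shrunk so the total
    group SD matches the configured spread.
    """
    m = config.mean(var, dose)
    sd = config.sd(var, dose)
    n = injuries.size
    if sd == 0.0 and config.noise_sds.get(var, 0.0) == 0.0:
        return np.full(n, m)
    expo = config.injury_coupling * config.coupling_weights.get(var, 0.0)
    g = np.power(np.maximum(injuries, 0.0), expo)
    h = g / g.mean() if g.mean() > 0 else np.ones(n)
    dev = (h - 1.0) * config.effect(var, dose)
    dev_sd = float(dev.std())
    if dev_sd > sd > 0:
        dev *= sd / dev_sd
        resid_sd = 0.0
    else:
        resid_sd = float(np.sqrt(max(sd**2 - dev_sd**2, 0.0)))
    vals = m + dev
    if resid_sd > 0:
        vals = vals + rng.normal(0.0, resid_sd, n)
    meas = config.noise_sds.get(var, 0.0)
    if meas > 0:
        vals = vals + rng.normal(0.0, meas, n)
    return vals


_CLIPS = {
    "cc_ibs": (0.05, None),
    "mcv": (0.0, None),
    "sf_pct": (2.0, 98.0),
    "lvedd_cm": (0.3, None),
    "collagen_pct": (0.05, 97.0),
}


def _clip(var: str, vals: np.ndarray) -> np.ndarray:
    lo, hi = _CLIPS.get(var, (None, None))
    return np.clip(vals, lo, hi)


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> Cohort:
    """Generate animal states, exam records and heart-level collagen truth."""
    seed = config.seed if seed is None else seed
    if config.injury_sigma > 0:
        z = substream(seed, "injury").standard_normal(config.n_baseline)
        injuries = np.exp(config.injury_sigma * z - config.injury_sigma**2 / 2)
    else:
        injuries = np.ones(config.n_baseline)
    animals, exam_sets = _plan_fates(config, injuries, substream(seed, "fates"))
    state = {a.animal_id: a for a in animals}

    rng_vals = substream(seed, "values")
    rows = []
    for dose in config.dose_schedule:
        members = exam_sets.get(dose, [])
        if not members:
            continue
        s = np.array([state[i].latent_injury for i in members])
        cols = {
            var: _clip(var, _draw_group(config, var, dose, s, rng_vals))
            for var in EXAM_VARIABLES
        }
        for k, i in enumerate(members):
            lvedd = cols["lvedd_cm"][k]
            rows.append(
                {
                    "animal_id": i,
                    "dose_mg_per_kg": dose,
                    "cc_ibs": cols["cc_ibs"][k],
                    "mcv": cols["mcv"][k],
                    "sf_pct": cols["sf_pct"][k],
                    "lvedd_cm": lvedd,
                    "lvesd_cm": lvedd * (1.0 - cols["sf_pct"][k] / 100.0),
                    "hr_bpm": config.heart_rate_bpm,
                }
            )
    exams = pd.DataFrame(rows)

    rng_col = substream(seed, "collagen")
    heart_rows = []
    for dose in config.dose_schedule:
        sac = sorted(a.animal_id for a in animals if a.sacrificed_at == dose)
        if not sac:
            continue
        if dose not in config.group_means["collagen_pct"]:
            raise ConfigurationError(f"no collagen group mean configured at dose {dose}")
        s = np.array([state[i].latent_injury for i in sac])
        vals = _clip("collagen_pct", _draw_group(config, "collagen_pct", dose, s, rng_col))
        for i, v in zip(sac, vals):
            state[i].true_collagen_pct = float(v)
            heart_rows.append(
                {"animal_id": i, "dose_mg_per_kg": dose, "true_collagen_pct": float(v)}
            )
    hearts = pd.DataFrame(heart_rows)

    return Cohort(config=config, seed=seed, animals=animals, exams=exams, hearts=hearts)


# ---------------------------------------------------------------------------
# raw measurement fixtures


def frames_per_cycle(config: GeneratorConfig) -> float:
    return config.frame_rate_hz * 60.0 / config.heart_rate_bpm


def _expected_value(config: GeneratorConfig, var: str, dose: float, injury: float) -> float:
    """Single-animal expectation of ``var`` at ``dose`` under the latent model.

    ``baseline + effect * h`` with the positive gain ``h = s**(coupling*w)``
    normalized by its log-normal population mean (so a population-average
    animal sits on the group mean). The gain is clamped to a dose-independent
    range, preserving trajectory monotonicity; a zero-injury animal keeps a
    flat trajectory.
    """
    expo = config.injury_coupling * config.coupling_weights.get(var, 0.0)
    if injury <= 0:
        h = 0.0
    else:
        # E[s**k] = exp(k*(k-1)*sigma^2/2) for s ~ LogNormal with mean 1
        norm = float(np.exp(expo * (expo - 1) * config.injury_sigma**2 / 2.0))
        h = min(injury**expo / norm, 10.0)
    base = config.mean(var, config.dose_schedule[0])
    return base + config.effect(var, dose) * h


def generate_ibs_trace(
    animal: AnimalState,
    dose: float,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    cc_ibs: Optional[float] = None,
    mcv: Optional[float] = None,
) -> Tuple[IBSTrace, IBSTrace]:
    """Synthesize a tissue IBS trace plus its matched phantom reference.

    The tissue trace is ``baseline + (MCV/2)*cos(2*pi*HR*t) + noise`` over
    ``config.trace_cycles`` cardiac cycles, with the baseline level chosen so
    that the dB-scale mean divided by the phantom level equals the target
    CC-IBS. Targets default to the animal's expected values at ``dose``
    under the latent-injury model (population-centered).
    """
    if dose not in config.dose_schedule:
        raise InputError(f"dose {dose} not in the exam schedule")
    if animal.alive_through_dose < dose:
        raise InputError(f"animal {animal.animal_id} was not alive at dose {dose}")
    fpc = frames_per_cycle(config)
    if fpc < 4:
        raise SamplingError(
            f"{fpc:.2f} frames/cycle cannot resolve the cardiac cycle (need >= 4)"
        )
    if rng is None:
        rng = substream(config.seed, f"trace/{animal.animal_id}/{dose:g}")
    if cc_ibs is None:
        cc_ibs = _expected_value(config, "cc_ibs", dose, animal.latent_injury)
    if mcv is None:
        mcv = max(_expected_value(config, "mcv", dose, animal.latent_injury), 0.0)

    n = int(round(config.trace_cycles * fpc))
    t = np.arange(n) / config.frame_rate_hz
    freq = config.heart_rate_bpm / 60.0
    baseline = cc_ibs * config.phantom_level_db
    tissue_vals = baseline + (mcv / 2.0) * np.cos(2.0 * np.pi * freq * t)
    noise = config.noise_sds.get("trace_db", 0.0)
    if noise > 0:
        tissue_vals = tissue_vals + rng.normal(0.0, noise, n)
    phantom_vals = np.full(n, config.phantom_level_db)
    pnoise = config.noise_sds.get("phantom_db", 0.0)
    if pnoise > 0:
        phantom_vals = phantom_vals + rng.normal(0.0, pnoise, n)
    common = dict(depth_cm=config.depth_cm, heart_rate_bpm=config.heart_rate_bpm)
    return (
        IBSTrace(time_s=t, intensity_db=tissue_vals, source="tissue", **common),
        IBSTrace(time_s=t, intensity_db=phantom_vals, source="phantom", **common),
    )


def generate_mmode(
    animal: AnimalState,
    dose: float,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    sf_pct: Optional[float] = None,
    lvedd_cm: Optional[float] = None,
) -> List[MModeMeasurement]:
    """Three consecutive-cycle M-mode readings targeting the animal's SF."""
    if dose not in config.dose_schedule:
        raise InputError(f"dose {dose} not in the exam schedule")
    if rng is None:
        rng = substream(config.seed, f"mmode/{animal.animal_id}/{dose:g}")
    if sf_pct is None:
        sf_pct = _expected_value(config, "sf_pct", dose, animal.latent_injury)
    if not 0.0 < sf_pct < 100.0:
        raise ConfigurationError(f"target shortening fraction {sf_pct}% outside (0, 100)")
    if lvedd_cm is None:
        lvedd_cm = config.mean("lvedd_cm", dose)
    lvesd_cm = lvedd_cm * (1.0 - sf_pct / 100.0)
    jitter = config.noise_sds.get("mmode_cycle_cm", 0.0)
    cycles = []
    for c in range(3):
        d_edd = lvedd_cm + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        d_esd = lvesd_cm + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        d_esd = min(d_esd, d_edd - 1e-3)
        cycles.append(
            MModeMeasurement(
                lvedd_cm=d_edd,
                lvesd_cm=max(d_esd, 1e-3),
                ivs_cm=config.ivs_cm,
                pw_cm=config.pw_cm,
                heart_rate_bpm=config.heart_rate_bpm,
                cycle_index=c,
            )
        )
    return cycles


def generate_histology_fields(
    animal: AnimalState,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[HistologyField]:
    """Stained-section field images with known collagen fraction.

    Collagen-positive pixels are placed Bernoulli(p) per pixel, so the mean
    true fraction across fields matches the animal's terminal collagen
    percentage up to binomial sampling error. With zero pixel noise the
    positive-pixel count per field is set deterministically to round(p*N)
    and intensities are noiseless (degenerate mode used by exact-recovery
    checks).
    """
    if animal.sacrificed_at is None:
        raise InputError(f"animal {animal.animal_id} was not sacrificed; no histology")
    if animal.true_collagen_pct is None:
        raise InputError(f"animal {animal.animal_id} has no terminal collagen value")
    if rng is None:
        rng = substream(config.seed, f"histology/{animal.animal_id}")
    p = animal.true_collagen_pct / 100.0
    size = config.hist_field_size
    noise = config.noise_sds.get("pixel", 0.0)
    fields = []
    for k in range(config.hist_n_fields):
        if noise == 0.0:
            n_pos = int(round(p * size * size))
            flat = np.zeros(size * size, dtype=bool)
            flat[:n_pos] = True
            mask = flat.reshape(size, size)
        else:
            mask = rng.random((size, size)) < p
        image = np.where(mask, config.hist_stain_level, config.hist_background_level)
        if noise > 0:
            image = image + rng.normal(0.0, noise, (size, size))
        if config.hist_blur_sigma > 0:
            from skimage.filters import gaussian

            image = gaussian(image, sigma=config.hist_blur_sigma)
        image = np.clip(image, 0.0, 1.0)
        fields.append(
            HistologyField(image=image, mask=mask, field_id=k + 1, animal_id=animal.animal_id)
        )
    return fields


# ---------------------------------------------------------------------------
# dataset output


def _status(animal: AnimalState, dose: float, examined: bool) -> str:
    if examined and animal.sacrificed_at == dose:
        return "examined_sacrificed"
    if examined:
        return "examined"
    if animal.sacrificed_at == dose:
        return "sacrificed"
    if animal.alive_through_dose >= dose and (
        animal.sacrificed_at is None or animal.sacrificed_at > dose
    ):
        return "alive_unexamined"
    return "dead"


def write_cohort(cohort: Cohort, out_dir: str | Path, write_assets: bool = True) -> Path:
    """Write the dataset directory: tables, traces, histology images, truth.

    With ``write_assets=False`` only the tabular records and truth are
    written (fast mode for statistical studies that do not need the raw
    trace/image fixtures).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = cohort.config

    config.to_json(out / "config.json")

    examined = {
        (int(r.animal_id), float(r.dose_mg_per_kg)) for r in cohort.exams.itertuples()
    }
    status_rows = [
        {
            "animal_id": a.animal_id,
            "dose_mg_per_kg": d,
            "status": _status(a, d, (a.animal_id, d) in examined),
        }
        for a in cohort.animals
        for d in config.dose_schedule
    ]
    pd.DataFrame(status_rows).to_csv(out / "animals.csv", index=False)

    mmode_rows = []
    for r in cohort.exams.itertuples():
        animal = cohort.animal(int(r.animal_id))
        rng = substream(cohort.seed, f"mmode/{animal.animal_id}/{r.dose_mg_per_kg:g}")
        for c in generate_mmode(
            animal, float(r.dose_mg_per_kg), config, rng,
            sf_pct=float(r.sf_pct), lvedd_cm=float(r.lvedd_cm),
        ):
            mmode_rows.append(
                {
                    "animal_id": animal.animal_id,
                    "dose_mg_per_kg": r.dose_mg_per_kg,
                    "cycle": c.cycle_index,
                    "lvedd_cm": c.lvedd_cm,
                    "lvesd_cm": c.lvesd_cm,
                    "ivs_cm": c.ivs_cm,
                    "pw_cm": c.pw_cm,
                    "hr_bpm": c.heart_rate_bpm,
                }
            )
    pd.DataFrame(mmode_rows).to_csv(out / "mmode.csv", index=False, float_format="%.10g")

    # exam-level drawn values (targets); the analysis stages recompute the
    # indices from the raw fixtures when present
    cohort.exams.to_csv(out / "records.csv", index=False, float_format="%.10g")
    cohort.hearts.to_csv(out / "hearts.csv", index=False, float_format="%.10g")

    if write_assets:
        import imageio.v3 as iio

        (out / "traces").mkdir(exist_ok=True)
        (out / "phantom").mkdir(exist_ok=True)
        for r in cohort.exams.itertuples():
            animal = cohort.animal(int(r.animal_id))
            dose = float(r.dose_mg_per_kg)
            rng = substream(cohort.seed, f"trace/{animal.animal_id}/{dose:g}")
            tissue, phantom = generate_ibs_trace(
                animal, dose, config, rng, cc_ibs=float(r.cc_ibs), mcv=float(r.mcv)
            )
            stem = f"{animal.animal_id}_{dose:g}.csv"
            tissue.to_csv(out / "traces" / stem)
            phantom.to_csv(out / "phantom" / stem)

        (out / "histology").mkdir(exist_ok=True)
        for a in cohort.animals:
            if a.sacrificed_at is None:
                continue
            rng = substream(cohort.seed, f"histology/{a.animal_id}")
            for f in generate_histology_fields(a, config, rng):
                img8 = (np.clip(f.image, 0, 1) * 255).astype(np.uint8)
                iio.imwrite(out / "histology" / f"{a.animal_id}_field{f.field_id}.png", img8)
                iio.imwrite(
                    out / "histology" / f"{a.animal_id}_field{f.field_id}_mask.png",
                    (f.mask.astype(np.uint8) * 255),
                )

    truth = {
        "seed": cohort.seed,
        "config_hash": config.content_hash(),
        "animals": [
            {
                "animal_id": a.animal_id,
                "latent_injury": a.latent_injury,
                "alive_through_dose": a.alive_through_dose,
                "sacrificed_at": a.sacrificed_at,
                "true_collagen_pct": a.true_collagen_pct,
                "exam_doses": a.exam_doses,
            }
            for a in cohort.animals
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out
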