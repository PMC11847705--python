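"""Seeded synthetic EHR + omics cohorts driven by a shared latent state.

Each patient carries a latent vector ``z ~ N(0, I_k)`` that drives all three
observed layers, mimicking the situation where clinical events, circulating
analytes and the outcome are expressions of one underlying physiological
state:

* coded events — on each day ``t`` of the horizon, code ``c`` fires with
  probability ``logistic(u_c . z + b_c + delta_t)``, where ``b_c`` sets the
  marginal base rate and ``delta_t`` is a linear drift toward the anchor day
  (e.g. codes intensifying toward delivery);
* omics — ``x = A z + eps`` with isotropic Gaussian noise, one draw per
  sample;
* outcome — continuous ``y = w . z + eta``, or a Bernoulli draw through a
  logistic link whose intercept is solved to hit a target prevalence.

The large pretraining cohort has EHR and labels only; the small omics cohort
additionally has one or more sampled omics vectors per patient with
sampling days drawn within the last ``sample_window`` days before the
anchor. Pretraining records emulate the sampling design by cutting their
history at a random day in the same span. Everything is deterministic given
``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit, logit
from scipy.optimize import brentq

from .cohort_io import CohortBundle, PatientRecord

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "oracle_r2"]


@dataclass
class SyntheticConfig:
    """Desk-scale defaults: a cohort comparison runs in minutes on one CPU."""

    n_pretrain: int = 2000
    n_omics: int = 80
    vocab_size: int = 200
    n_analytes: int = 50
    latent_dim: int = 4
    horizon: int = 20           # observed days per patient
    code_base_rate: float = 0.01
    loading_scale: float = 1.0
    omics_noise: float = 1.2
    outcome_noise: float = 0.5
    outcome_type: str = "continuous"   # or "binary"
    prevalence: float = 0.2            # binary outcomes only
    drift_slope: float = 1.0           # code-rate ramp toward the anchor day
    samples_per_omics_patient: int = 2
    sample_window: int = 10            # sampling days fall in the last such days
    seed: int = 0

    def __post_init__(self):
        for name in ("n_pretrain", "n_omics", "vocab_size", "n_analytes",
                     "latent_dim", "horizon", "samples_per_omics_patient"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.code_base_rate < 1.0:
            raise ValueError("code_base_rate must be in (0, 1)")
        if self.omics_noise < 0 or self.outcome_noise < 0:
            raise ValueError("noise scales must be >= 0")
        if self.outcome_type not in {"continuous", "binary"}:
            raise ValueError("outcome_type must be continuous or binary")


@dataclass
class GroundTruth:
    Z: np.ndarray            # (n_patients, k) latent states
    U: np.ndarray            # (V, k) code loadings
    A: np.ndarray            # (P, k) analyte loadings
    w: np.ndarray            # (k,) outcome weights
    w0: float                # outcome intercept (binary link)
    event_days: np.ndarray   # (n_patients,) anchor day per patient
    patient_ids: list[str]


def _solve_intercept(scores: np.ndarray, prevalence: float) -> float:
    """Intercept w0 with mean(logistic(scores + w0)) == prevalence."""
    f = lambda w0: expit(scores + w0).mean() - prevalence
    return brentq(f, -50.0, 50.0)


def oracle_r2(truth: GroundTruth, config: SyntheticConfig) -> float:
    """Population fraction of outcome variance explained by the latent state
    — the ceiling any predictor can reach: ||w||^2 / (||w||^2 + sigma_eta^2)."""
    if config.outcome_type != "continuous":
        raise ValueError("oracle_r2 is defined for continuous outcomes")
    s = float(truth.w @ truth.w)
    denom = s + config.outcome_noise**2
    return 0.0 if denom == 0 else s / denom


def generate(config: SyntheticConfig) -> tuple[CohortBundle, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    n = config.n_pretrain + config.n_omics
    k, V, P, T = (config.latent_dim, config.vocab_size,
                  config.n_analytes, config.horizon)

    Z = rng.standard_normal((n, k))
    U = rng.standard_normal((V, k)) * (config.loading_scale / np.sqrt(k))
    A = rng.standard_normal((P, k)) * (config.loading_scale / np.sqrt(k))
    w = rng.standard_normal(k)
    w = w / np.linalg.norm(w) if np.linalg.norm(w) > 0 else w

    anchor = T  # anchor event (delivery/diagnosis analogue) the day after T-1
    event_days = np.full(n, anchor)
    # linear ramp: most negative at the oldest day, 0 at the anchor
    delta = config.drift_slope * (np.arange(T) - anchor) / T  # (T,)
    b = logit(config.code_base_rate)

    scores = Z @ w  # (n,)
    if config.outcome_type == "continuous":
        w0 = 0.0
        y = scores + config.outcome_noise * rng.standard_normal(n)
    else:
        w0 = _solve_intercept(scores, config.prevalence)
        y = rng.random(n) < expit(scores + w0)
        if y.all() or not y.any():
            raise ValueError("degenerate labels (all one class); "
                             "increase n or adjust prevalence")
        y = y.astype(float)

    logits = Z @ U.T + b  # (n, V)
    patient_ids = [f"P{i:05d}" for i in range(n)]
    span = min(config.sample_window, T)

    def day_codes(i: int) -> list[tuple[int, list[str]]]:
        p = expit(logits[i][None, :] + delta[:, None])  # (T, V)
        hits = rng.random((T, V)) < p
        out = []
        for t in range(T):
            cs = np.flatnonzero(hits[t])
            if cs.size:
                out.append((t, [f"C{c:04d}" for c in cs]))
        return out

    pretraining: list[PatientRecord] = []
    omics: list[PatientRecord] = []
    analyte_names = [f"A{j:03d}" for j in range(P)]

    for i in range(n):
        events = day_codes(i)
        is_omics = i >= config.n_pretrain
        if not is_omics:
            cut = int(rng.integers(anchor - span, anchor + 1))
            wev = [(t, cs) for t, cs in events if t <= cut]
            pretraining.append(PatientRecord(
                patient_id=patient_ids[i], windowed_events=wev,
                outcome=float(y[i]), cohort="pretraining",
                window=(0, cut)))
        else:
            s_days = rng.integers(anchor - span, anchor + 1,
                                  size=config.samples_per_omics_patient)
            for j, sday in enumerate(sorted(int(d) for d in s_days)):
                x = A @ Z[i] + config.omics_noise * rng.standard_normal(P)
                wev = [(t, cs) for t, cs in events if t <= sday]
                omics.append(PatientRecord(
                    patient_id=patient_ids[i], windowed_events=wev,
                    outcome=float(y[i]), cohort="omics",
                    record_id=f"{patient_ids[i]}_s{j}",
                    omics_vector=x, window=(0, sday)))

    truth = GroundTruth(Z=Z, U=U, A=A, w=w, w0=float(w0),
                        event_days=event_days, patient_ids=patient_ids)
    manifest = {"generator": "synthetic_cohort", **asdict(config),
                "n_pretraining": len(pretraining),
                "n_omics_records": len(omics),
                "n_analytes": P}
    bundle = CohortBundle(pretraining=pretraining, omics=omics,
                          analyte_names=analyte_names, manifest=manifest)
    return bundle, truth
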