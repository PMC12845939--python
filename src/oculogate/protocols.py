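"""End-to-end evaluation protocols built from the package's own modules.

These are the synthetic benchmark experiments the package reports:

* a biometric verification experiment (enrolled identities, perturbed probe
  codes, shift-tolerant matching, FAR/FRR/EER), and
* the depressive-pattern discrimination experiment (default cohort, logistic
  feature model, participant-level split, test-set ROC AUC).
"""

from __future__ import annotations

import numpy as np

from . import irisid, screening
from .seqnet import participant_split
from .simgen import CohortConfig, IrisIdentityParams, generate_cohort, simulate_iris_image

__all__ = ["enroll_identity", "iris_verification_eer", "cohort_logistic_auc",
           "rule_screening_run", "LOGISTIC_FEATURES"]

LOGISTIC_FEATURES = ("PDA_neg", "PDA_pos", "FD", "SV")


def enroll_identity(identity_seed: int, dilation: float = 0.20,
                    n_bits: int = 512, render_seed: int = 0) -> irisid.IrisCode:
    """Run the full enrolment pipeline for one synthetic identity: render the
    eye image, locate the boundaries, rubber-sheet normalise, and encode."""
    n_radial = 16
    n_angular = n_bits // (2 * n_radial)
    params = IrisIdentityParams(identity_seed=identity_seed)
    img = simulate_iris_image(params, dilation=dilation, seed=render_seed)
    fit = irisid.locate_boundaries(img)
    tex = irisid.rubber_sheet(img, fit, n_radial=n_radial, n_angular=n_angular)
    code = irisid.encode(tex, n_bits=n_bits)
    code.identity = f"id{identity_seed:05d}"
    return code


def _perturb(code: irisid.IrisCode, flip_rate: float, rotation: int,
             rng: np.random.Generator) -> irisid.IrisCode:
    grid = np.roll(code.as_grid(), rotation, axis=1)
    flips = rng.random(grid.shape) < flip_rate
    bits = np.where(flips, 1 - grid, grid).astype(np.uint8)
    return irisid.IrisCode(bits=bits.ravel(), n_radial=code.n_radial,
                           n_angular=code.n_angular, identity=code.identity)


def iris_verification_eer(seed: int = 0, n_identities: int = 100,
                          n_samples: int = 5, flip_rate: float = 0.08,
                          max_rotation: int = 4, n_impostor_pairs: int = 10_000,
                          n_bits: int = 512, max_shift: int = 4
                          ) -> irisid.BiometricEval:
    """Synthetic verification experiment.

    Each identity is enrolled through the full image pipeline; its acquisition
    samples are the enrolled code under intra-class noise equivalent to
    independent bit perturbation at ``flip_rate`` plus rotation jitter within
    ``max_rotation`` angular positions.  All genuine pairs and
    ``n_impostor_pairs`` random impostor pairs are scored with the
    shift-tolerant Hamming distance.
    """
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    templates = []
    sample_ids = []
    sample_grids = []
    for i in range(n_identities):
        base = enroll_identity(identity_seed=int(rng.integers(2 ** 31)),
                               dilation=float(rng.uniform(0.10, 0.40)),
                               n_bits=n_bits,
                               render_seed=int(rng.integers(2 ** 31)))
        templates.append(base.as_grid().astype(bool))
        for _ in range(n_samples):
            rot = int(rng.integers(-max_rotation, max_rotation + 1))
            sample_ids.append(i)
            sample_grids.append(_perturb(base, flip_rate, rot, rng)
                                .as_grid().astype(bool))

    ids = np.array(sample_ids)
    grids = np.stack(sample_grids)
    tmpl = np.stack(templates)

    def batch_distance(sample_idx: np.ndarray, tmpl_idx: np.ndarray) -> np.ndarray:
        a = grids[sample_idx]
        best = np.ones(len(sample_idx))
        for s in range(-max_shift, max_shift + 1):
            d = (a != np.roll(tmpl[tmpl_idx], s, axis=2)).mean(axis=(1, 2, 3))
            best = np.minimum(best, d)
        return best

    # full genuine set: every acquisition sample against its own template
    genuine = batch_distance(np.arange(len(ids)), ids)

    m = len(ids)
    ia = rng.integers(0, m, size=2 * n_impostor_pairs)
    jt = rng.integers(0, n_identities, size=2 * n_impostor_pairs)
    keep = ids[ia] != jt
    ia, jt = ia[keep][:n_impostor_pairs], jt[keep][:n_impostor_pairs]
    impostor = batch_distance(ia, jt)

    return irisid.evaluate_biometrics(genuine, impostor)


def cohort_logistic_auc(seed: int = 0, cfg: CohortConfig | None = None,
                        features: tuple[str, ...] = LOGISTIC_FEATURES,
                        level: str = "latent"
                        ) -> tuple[float, screening.LogisticModel]:
    """One train/test replicate of the logistic discrimination experiment.

    Generates the (default) cohort with the given seed and fits the logistic
    feature model on a participant-level 70/15/15 split, returning the
    test-set ROC AUC together with the fitted model.  The validation fraction
    has no role for a logistic fit (no early stopping), so it is folded into
    training; the test fraction is untouched.  ``level='latent'`` uses the
    participant-level feature draws; ``level='session'`` uses the
    per-stimulus screening averages instead.
    """
    cfg = cfg or CohortConfig()
    cfg_seeded = CohortConfig(**{**cfg.__dict__, "seed": seed})
    cohort = generate_cohort(cfg_seeded)
    if level == "latent":
        import pandas as pd
        frame = pd.DataFrame(
            {p.pid: {**p.latent, "group": p.group} for p in cohort.participants}
        ).T
    else:
        frame = cohort.feature_frame()
    y = (frame["group"] == "depressed").astype(int)
    X = frame.loc[:, list(features)].to_numpy(dtype=float)

    groups = participant_split(frame.index, seed=seed)
    te = frame.index.isin(groups["test"])
    tr = ~te
    model = screening.fit_logistic(X[tr], y[tr].to_numpy(), feature_names=features)
    probs = model.predict(X[te])
    _, _, auc = screening.roc_auc(probs, y[te].to_numpy())
    return auc, model


def rule_screening_run(seed: int = 0, cfg: CohortConfig | None = None,
                       rule_cfg: screening.RuleConfig | None = None):
    """Full rule-based screening of a cohort against individual baselines.

    Returns (labels DataFrame, ConfusionMetrics) where predictions come from
    the 2-SD rule applied to each participant's screening stimuli z-scored
    against their own multi-state baseline profile.
    """
    import pandas as pd

    from .oculometrics import build_baseline, zscore

    cfg = cfg or CohortConfig()
    cfg_seeded = CohortConfig(**{**cfg.__dict__, "seed": seed})
    rule_cfg = rule_cfg or screening.RuleConfig()
    cohort = generate_cohort(cfg_seeded)
    rows = []
    for p in cohort.participants:
        # per-stimulus reference observations: the baseline SD must be on
        # the same scale as the per-stimulus screening values it z-scores
        ref_obs = [stim.features for s in p.reference_sessions
                   for stim in s.stimuli]
        ref_states = [s.state for s in p.reference_sessions
                      for _ in s.stimuli]
        profile = build_baseline(ref_obs, ref_states)
        stim_z = [(zscore(s.features, profile), s.valence)
                  for s in p.screening_session.stimuli]
        label, flags = screening.screen_participant(stim_z, rule_cfg)
        rows.append({"participant_id": p.pid, "group": p.group,
                     "rule_label": label, "n_flagged": sum(flags)})
    df = pd.DataFrame(rows)
    pred = df["rule_label"] == screening.LABEL_POSITIVE
    truth = df["group"] == "depressed"
    cm = screening.confusion_metrics(
        tn=int((~pred & ~truth).sum()), fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()), tp=int((pred & truth).sum()))
    return df, cm
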