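"""Decision procedure: map metric and test outcomes onto the aggregation
typology.

Verdicts, in increasing order of evidence required:

* ``no_aggregation`` — multi-individual captures are no more common than
  independent captures would make them;
* ``non_social_aggregation`` — individuals co-occur because they share an
  environmental driver (site, season), not because of each other;
* ``non_specific_social_group`` — conspecific presence matters but identity
  does not (trait assortment, local enhancement);
* ``specific_social_group`` — preferred companions recur across events,
  which requires individual recognition;
* ``undetermined`` — the lines of evidence conflict or are missing.

Each metric contributes one finding line; the verdict is the highest
typology level whose evidentiary bar is met, with specific > non-specific >
non-social precedence. All per-metric support flags are retained so mixed
regimes remain visible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

VERDICTS = ("no_aggregation", "non_social_aggregation",
            "non_specific_social_group", "specific_social_group",
            "undetermined")


@dataclass
class Thresholds:
    alpha: float = 0.05
    prevalence_threshold: float = 0.5
    site_fidelity_high: float = 0.9

    def __post_init__(self) -> None:
        for name in ("alpha", "prevalence_threshold", "site_fidelity_high"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def to_dict(self) -> dict:
        return {"alpha": self.alpha,
                "prevalence_threshold": self.prevalence_threshold,
                "site_fidelity_high": self.site_fidelity_high}


@dataclass
class Finding:
    metric: str
    observed: str
    supports: dict[str, bool | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"metric": self.metric, "observed": self.observed,
                "supports": dict(self.supports)}


@dataclass
class ClassificationLedger:
    findings: list[Finding]
    verdict: str
    thresholds: Thresholds
    rule_log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"verdict": self.verdict,
                "thresholds": self.thresholds.to_dict(),
                "findings": [f.to_dict() for f in self.findings],
                "rule_log": list(self.rule_log)}


def _get(d, *keys, default=None):
    cur = d
    for k in keys:
        if cur is None or k not in cur:
            return default
        cur = cur[k]
    return cur


def _sig(null_results: dict, name: str, alpha: float) -> bool | None:
    """True/False if the test ran; None if absent or degenerate."""
    res = (null_results or {}).get(name)
    if res is None:
        return None
    if hasattr(res, "p_value"):
        p, degenerate = res.p_value, res.degenerate
    else:
        p, degenerate = res.get("p_value"), res.get("degenerate", False)
    if degenerate or p is None:
        return None
    return p <= alpha


def apply_framework(
    metrics_report: dict,
    null_results: dict | None = None,
    model_fits: dict | None = None,
    thresholds: Thresholds | None = None,
) -> ClassificationLedger:
    """Apply the typology rules to upstream findings.

    ``metrics_report`` is the per-scale mapping from
    :func:`catchassoc.metrics.metrics_report`; ``null_results`` maps test
    names (``aggregation``, ``assortment_sex``, ``assortment_size``,
    ``companion``, optionally ``kin``) to NullResults (or their dicts);
    ``model_fits`` optionally maps labels to ModelFit objects, whose site and
    month terms feed the environmental-driver rule.
    """
    th = thresholds or Thresholds()
    null_results = null_results or {}
    log_lines: list[str] = []
    findings: list[Finding] = []

    # -- rule 1: aggregation at all? --------------------------------------
    prevalence = _get(metrics_report, "catch_size", "prevalence_multi")
    agg_sig = _sig(null_results, "aggregation", th.alpha)
    prevalence_high = (prevalence is not None
                       and prevalence >= th.prevalence_threshold)
    agg_supported = bool(agg_sig) or prevalence_high
    if prevalence is None and agg_sig is None:
        raise ValueError("metric i (catch sizes) missing: cannot classify")
    log_lines.append(
        f"rule1 aggregation: prevalence_multi={prevalence!r} "
        f"(threshold {th.prevalence_threshold}), aggregation_test_sig="
        f"{agg_sig} -> supported={agg_supported}")
    findings.append(Finding(
        "i_catch_size",
        f"multi-capture prevalence {prevalence:.2f}" if prevalence is not None
        else "not assessed",
        {"aggregation": agg_supported}))

    # -- rule 2: specific companions --------------------------------------
    companion_sig = _sig(null_results, "companion", th.alpha)
    rec = _get(metrics_report, "recapture") or {}
    n_rec = rec.get("n_recapture_events", 0)
    frac_together = rec.get("fraction_recaptured_together")
    obs_iv = (f"{n_rec} recapture events, "
              f"{rec.get('n_recaptured_together', 0)} recaptured together"
              if n_rec else "no recaptures")
    findings.append(Finding(
        "iv_individual_identity", obs_iv,
        {"specific_social": companion_sig}))
    log_lines.append(f"rule2 companion test significant={companion_sig} "
                     f"(recaptured together fraction={frac_together!r})")

    # -- rule 3: trait / kin assortment ------------------------------------
    sex_sig = _sig(null_results, "assortment_sex", th.alpha)
    size_sig = _sig(null_results, "assortment_size", th.alpha)
    kin_sig = _sig(null_results, "kin", th.alpha)
    assort_sig = any(v for v in (sex_sig, size_sig, kin_sig) if v)
    findings.append(Finding(
        "ii_phenotypic_traits",
        f"sex assortment sig={sex_sig}, size assortment sig={size_sig}",
        {"non_specific_social": bool(sex_sig or size_sig)}))
    kin = _get(metrics_report, "kin")
    findings.append(Finding(
        "v_kin_structure",
        (f"{kin['n_kin_pairs']}/{kin['n_cocaptured_pairs_assessed']} assessed "
         "recaptured-together pairs are siblings" if kin else "not assessed"),
        {"non_specific_social": kin_sig}))
    log_lines.append(f"rule3 assortment: sex={sex_sig} size={size_sig} "
                     f"kin_test={kin_sig} -> any={assort_sig}")

    # -- rule 4: environmental / site dominance ----------------------------
    site_fid = rec.get("site_fidelity_fraction")
    site_faithful = site_fid is not None and site_fid >= th.site_fidelity_high
    model_env = None
    if model_fits:
        model_env = False
        for label, fit in model_fits.items():
            terms = getattr(fit, "terms", None) or {}
            for tname in ("site", "month"):
                t = terms.get(tname)
                if t is not None and t.p_value <= th.alpha:
                    model_env = True
                    log_lines.append(
                        f"rule4 model {label}: {tname} term significant "
                        f"(p={t.p_value:.3g})")
    env_dominant = site_faithful or bool(model_env)
    findings.append(Finding(
        "iii_drivers",
        (f"site fidelity {site_fid:.2f}" if site_fid is not None
         else "site fidelity not assessed")
        + (f"; site/month model terms significant={model_env}"
           if model_env is not None else ""),
        {"non_social": env_dominant}))
    log_lines.append(f"rule4 environment: site_fidelity={site_fid!r} "
                     f"model_site_month={model_env} -> {env_dominant}")

    # -- verdict ----------------------------------------------------------
    if not agg_supported:
        verdict = "no_aggregation"
        if companion_sig or assort_sig:
            log_lines.append("conflict: social signal without aggregation "
                             "support; aggregation gate takes precedence")
    elif companion_sig:
        verdict = "specific_social_group"
    elif assort_sig:
        verdict = "non_specific_social_group"
    elif env_dominant:
        verdict = "non_social_aggregation"
    else:
        verdict = "undetermined"
        log_lines.append("aggregation supported but no driver identified")
    log_lines.append(f"verdict: {verdict}")
    return ClassificationLedger(findings=findings, verdict=verdict,
                                thresholds=th, rule_log=log_lines)


def render_report(
    ledger: ClassificationLedger,
    metrics_report: dict | None = None,
    null_results: dict | None = None,
    ground_truth: dict | None = None,
) -> str:
    """Markdown report: one row per metric, hypothesis-support columns."""
    if not ledger.findings:
        raise ValueError("empty ledger: nothing to report")
    lines = ["# Aggregation classification report", ""]
    if ground_truth:
        lines += [f"Generating scenario (ground truth): "
                  f"`{ground_truth.get('scenario')}` — expected verdict "
                  f"`{ground_truth.get('expected_verdict')}`", ""]
    lines += [f"**Verdict: `{ledger.verdict}`**", ""]
    lines += ["| Metric | Finding | Supports |", "|---|---|---|"]
    for f in ledger.findings:
        support = ", ".join(
            f"{k}: {'yes' if v else 'no' if v is False else 'n/a'}"
            for k, v in f.supports.items()) or "—"
        lines.append(f"| {f.metric} | {f.observed} | {support} |")
    if null_results:
        lines += ["", "## Permutation tests", "",
                  "| Test | Observed | p | Direction |", "|---|---|---|---|"]
        for name in sorted(null_results):
            r = null_results[name]
            d = r.to_dict() if hasattr(r, "to_dict") else dict(r)
            lines.append(
                f"| {name} | {d['observed']:.4g} | {d['p_value']:.4g} "
                f"| {d['direction']} |")
    lines += ["", "## Rule log", ""]
    lines += [f"- {line}" for line in ledger.rule_log]
    lines.append("")
    return "\n".join(lines)
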