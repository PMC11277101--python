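"""Full two-diet analysis: trait tables, growth parameters, survival.

``run_full_analysis`` reproduces the shape of a prey-suitability study
report: per-diet biological-trait summaries with pairwise tests chosen
by the usual decision rule (Shapiro-Wilk normality in each group and
Levene homogeneity at alpha, then Student's t, otherwise Mann-Whitney),
a chi-square for immature survival, exact binomial sex-ratio tests
against an even ratio, jackknifed growth parameters compared on their
pseudo-values, and Kaplan-Meier curves with a log-rank test over the
whole life cycle.

The report is deterministic: identical inputs give byte-identical JSON.
Provenance carries content hashes of the inputs and the package
version; wall-clock timestamps are logged, not embedded.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .records import CohortDataset
from .life_table import TraitSummary, summarize_traits
from .jackknife import JackknifeResult, compare_jackknife, jackknife_demography
from .inference import (TestResult, exact_binomial, levene_test,
                        mann_whitney_u, pearson_chi2_2x2, pooled_t_test,
                        shapiro_normality)
from .survival import cohort_durations, km_fit, log_rank, mean_lifespan
from .demography import PARAM_NAMES

__all__ = ["AnalysisOptions", "AnalysisReport", "run_full_analysis",
           "render_report", "significance_letters"]

log = logging.getLogger("cohortdemog.pipeline")

COMPARED_TRAITS = [
    "incubation_time", "immature_development_time", "preoviposition_time",
    "fecundity", "fertility", "oviposition_rate", "oviposition_period",
    "female_weight", "male_weight",
]


@dataclass
class AnalysisOptions:
    """Knobs for the pipeline: significance level, forced test choices
    (trait name -> 't_test' | 'mann_whitney'), lx estimator."""

    alpha: float = 0.05
    force_tests: dict = field(default_factory=dict)
    product_limit: bool = True
    sex_ratio_null: float = 0.5


@dataclass
class AnalysisReport:
    """Machine-readable result of the two-diet analysis (plain-JSON body)."""

    body: dict

    def to_dict(self) -> dict:
        return self.body

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(body=d)

    def to_json(self) -> str:
        return json.dumps(self.body, sort_keys=True, indent=1,
                          separators=(",", ": "))

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# serialization helpers (plain built-ins only, so JSON round-trips exactly)

def _round(x, nd=12):
    if x is None:
        return None
    x = float(x)
    if math.isnan(x):
        return "nan"
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return round(x, nd)


def _trait_dict(t: TraitSummary) -> dict:
    return {"trait": t.trait, "mean": _round(t.mean), "se": _round(t.se),
            "n": int(t.n), "unit": t.unit,
            "extra": list(t.extra) if t.extra else None,
            "values": [_round(v) for v in t.values] if t.values else None}


def _test_dict(r: TestResult) -> dict:
    return {"method": r.method, "statistic": _round(r.statistic),
            "p": _round(r.p), "df": _round(r.df) if r.df is not None else None,
            "n_per_group": list(r.n_per_group) if r.n_per_group else None,
            "ci": [_round(r.ci[0]), _round(r.ci[1])] if r.ci else None,
            "note": r.note}


def _jk_dict(r: JackknifeResult) -> dict:
    return {"statistic": r.statistic, "estimate_all": _round(r.estimate_all),
            "mean": _round(r.mean), "se": _round(r.se), "n": int(r.n),
            "pseudo_values": [_round(v) for v in r.pseudo_values],
            "flags": list(r.flags)}


def _dataset_hash(dataset: CohortDataset) -> str:
    return hashlib.sha256(repr(dataset).encode()).hexdigest()[:16]


def significance_letters(mean_a: float, mean_b: float, p: float,
                         alpha: float = 0.05) -> tuple[str, str]:
    """Table-style letters: equal groups share 'a'; when the test is
    significant the larger mean gets 'a', the smaller 'b'."""
    if not (p < alpha):
        return "a", "a"
    return ("a", "b") if mean_a >= mean_b else ("b", "a")


# ---------------------------------------------------------------------------

def _select_and_run(name: str, xa, xb, options: AnalysisOptions,
                    selection_log: list) -> TestResult:
    """Decision rule: t-test when both groups pass Shapiro-Wilk and the
    pair passes Levene at alpha, else Mann-Whitney; overridable."""
    forced = options.force_tests.get(name)
    if forced:
        choice, reason = forced, "forced by options"
    else:
        sha, shb = shapiro_normality(xa), shapiro_normality(xb)
        lev = levene_test(xa, xb)
        normal = (not math.isnan(sha.p) and sha.p >= options.alpha
                  and not math.isnan(shb.p) and shb.p >= options.alpha)
        homoge = lev.p >= options.alpha
        choice = "t_test" if (normal and homoge) else "mann_whitney"
        reason = (f"shapiro_p=({_round(sha.p, 4)},{_round(shb.p, 4)}), "
                  f"levene_p={_round(lev.p, 4)}")
    selection_log.append({"comparison": name, "test": choice,
                          "reason": reason})
    log.info("comparison %s -> %s (%s)", name, choice, reason)
    if choice == "t_test":
        return pooled_t_test(xa, xb)
    return mann_whitney_u(xa, xb)


def run_full_analysis(cohort_a: CohortDataset, cohort_b: CohortDataset,
                      options: Optional[AnalysisOptions] = None) -> AnalysisReport:
    """The complete two-diet comparison; see the module docstring."""
    options = options or AnalysisOptions()
    if cohort_a.diet == cohort_b.diet:
        raise ValueError("the two cohorts must carry distinct diet labels")
    for c in (cohort_a, cohort_b):
        c.validate()
    diets = (cohort_a.diet, cohort_b.diet)
    selection_log: list[dict] = []
    body: dict = {
        "diets": list(diets),
        "traits": {}, "trait_tests": {}, "sex_ratio_tests": {},
        "demography": {}, "demography_tests": {},
        "survival": {}, "diagnostics": [],
        "provenance": {
            "package": "cohortdemog", "version": __version__,
            "input_hashes": {cohort_a.diet: _dataset_hash(cohort_a),
                             cohort_b.diet: _dataset_hash(cohort_b)},
            "alpha": options.alpha,
        },
    }

    # --- trait summaries and pairwise tests --------------------------------
    traits = {}
    for cohort in (cohort_a, cohort_b):
        summary = summarize_traits(cohort)
        traits[cohort.diet] = {t.trait: t for t in summary}
        body["traits"][cohort.diet] = [_trait_dict(t) for t in summary]

    for name in COMPARED_TRAITS:
        ta = traits[diets[0]].get(name)
        tb = traits[diets[1]].get(name)
        if ta is None or tb is None or not ta.values or not tb.values:
            body["diagnostics"].append(f"trait '{name}' not compared: "
                                       "missing in one or both cohorts")
            continue
        if len(ta.values) < 2 or len(tb.values) < 2:
            body["diagnostics"].append(f"trait '{name}' not compared: "
                                       "fewer than 2 values in a group")
            continue
        res = _select_and_run(name, ta.values, tb.values, options,
                              selection_log)
        body["trait_tests"][name] = _test_dict(res)

    sa = traits[diets[0]].get("immature_survival")
    sb = traits[diets[1]].get("immature_survival")
    if sa and sb and sa.extra and sb.extra:
        ka, na = sa.extra
        kb, nb = sb.extra
        try:
            res = pearson_chi2_2x2(ka, na - ka, kb, nb - kb)
        except ValueError as exc:   # e.g. nobody died in either cohort
            body["diagnostics"].append(f"immature survival not compared: {exc}")
        else:
            body["trait_tests"]["immature_survival"] = _test_dict(res)
            selection_log.append({"comparison": "immature_survival",
                                  "test": "pearson_chi2",
                                  "reason": "count data"})

    for cohort in (cohort_a, cohort_b):
        t = traits[cohort.diet].get("sex_ratio_percent_female")
        if t and t.extra:
            nf, nm = t.extra
            n_males = nm
            res = exact_binomial(n_males, nf + nm, options.sex_ratio_null)
            body["sex_ratio_tests"][cohort.diet] = _test_dict(res)

    # --- demography ---------------------------------------------------------
    jk = {}
    for cohort in (cohort_a, cohort_b):
        if len(cohort.fertile_females()) < 2:
            body["diagnostics"].append(
                f"cohort '{cohort.diet}' has fewer than 2 fertile females: "
                "demographic section omitted")
            continue
        results = jackknife_demography(cohort)
        jk[cohort.diet] = results
        body["demography"][cohort.diet] = {p: _jk_dict(r)
                                           for p, r in results.items()}
    if len(jk) == 2:
        for p in PARAM_NAMES:
            ra, rb = jk[diets[0]][p], jk[diets[1]][p]
            forced = options.force_tests.get(p)
            if forced:
                res = compare_jackknife(ra, rb, method=forced)
                selection_log.append({"comparison": p, "test": forced,
                                      "reason": "forced by options"})
            else:
                res = _select_and_run(p, ra.pseudo_values, rb.pseudo_values,
                                      options, selection_log)
            body["demography_tests"][p] = _test_dict(res)

    # --- survival -----------------------------------------------------------
    dur = {}
    for cohort in (cohort_a, cohort_b):
        d, e = cohort_durations(cohort)
        dur[cohort.diet] = (d, e)
        curve = km_fit(d, e)
        body["survival"][cohort.diet] = {
            "mean_lifespan": _round(mean_lifespan(d, e)),
            "km": {"times": [_round(t) for t in curve.times],
                   "surv": [_round(s) for s in curve.surv],
                   "ci_low": [_round(v) for v in curve.ci_low],
                   "ci_high": [_round(v) for v in curve.ci_high],
                   "n_risk": [int(v) for v in curve.n_risk],
                   "n_event": [int(v) for v in curve.n_event]},
        }
    (da, ea), (db, eb) = dur[diets[0]], dur[diets[1]]
    body["survival"]["log_rank"] = _test_dict(log_rank(da, ea, db, eb))

    body["selection_log"] = selection_log
    return AnalysisReport(body=body)


# ---------------------------------------------------------------------------
# rendering

def render_report(report: AnalysisReport, fmt: str, out_dir) -> list[str]:
    """Write the report as 'json', 'markdown' or 'tsv-bundle'; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    body = report.body
    paths = []
    if fmt == "json":
        path = os.path.join(out_dir, "report.json")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(report.to_json())
        paths.append(path)
    elif fmt == "markdown":
        path = os.path.join(out_dir, "report.md")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_render_markdown(body))
        paths.append(path)
    elif fmt == "tsv-bundle":
        paths.extend(_render_tsv(body, out_dir))
    else:
        raise ValueError(f"unknown format '{fmt}'")
    return paths


def _fmt_ms(mean, se, nd=3):
    if se is None:
        return f"{mean:.{nd}f}"
    return f"{mean:.{nd}f} ± {se:.{nd}f}"


def _letters_for(body, section, name, mean_key):
    diets = body["diets"]
    test = body[section].get(name)
    alpha = body["provenance"]["alpha"]
    if section == "trait_tests":
        rows = {d: next((t for t in body["traits"][d] if t["trait"] == name),
                        None) for d in diets}
        means = [rows[d]["mean"] if rows[d] else math.nan for d in diets]
    else:
        means = [body["demography"][d][name][mean_key] for d in diets]
    if test is None or any(math.isnan(m) for m in means):
        return ("", "")
    p = test["p"] if isinstance(test["p"], float) else math.nan
    if math.isnan(p):
        return ("", "")
    return significance_letters(means[0], means[1], p, alpha)


def _render_markdown(body) -> str:
    diets = body["diets"]
    lines = [f"# Two-diet cohort analysis: {diets[0]} vs {diets[1]}", ""]
    lines.append("## Biological traits")
    lines.append(f"| trait | {diets[0]} | {diets[1]} | test | p |")
    lines.append("|---|---|---|---|---|")
    t_by = {d: {t["trait"]: t for t in body["traits"][d]} for d in diets}
    all_traits = list(dict.fromkeys(
        [t["trait"] for d in diets for t in body["traits"][d]]))
    for name in all_traits:
        ta, tb = t_by[diets[0]].get(name), t_by[diets[1]].get(name)
        test = body["trait_tests"].get(name)
        la, lb = _letters_for(body, "trait_tests", name, "mean")
        cells = []
        for t, letter in ((ta, la), (tb, lb)):
            if t is None:
                cells.append("—")
            else:
                se = t["se"] if isinstance(t["se"], float) else None
                cells.append(f"{_fmt_ms(t['mean'], se, 2)} {letter} "
                             f"(n={t['n']})")
        if test:
            tcell = test["method"]
            pcell = f"{test['p']:.4f}" if isinstance(test["p"], float) else "—"
        else:
            tcell = pcell = "—"
        lines.append(f"| {name} | {cells[0]} | {cells[1]} | {tcell} | {pcell} |")
    lines.append("")
    if body["demography"]:
        lines.append("## Population growth parameters (jackknife mean ± SE)")
        lines.append(f"| parameter | {diets[0]} | {diets[1]} | test | p |")
        lines.append("|---|---|---|---|---|")
        for p in PARAM_NAMES:
            cells = []
            la, lb = ("", "")
            if p in body["demography_tests"]:
                la, lb = _letters_for(body, "demography_tests", p, "mean")
            for d, letter in zip(diets, (la, lb)):
                jk = body["demography"].get(d, {}).get(p)
                cells.append("—" if jk is None
                             else f"{_fmt_ms(jk['mean'], jk['se'])} {letter}")
            test = body["demography_tests"].get(p)
            if test:
                tcell = test["method"]
                pcell = (f"{test['p']:.4f}"
                         if isinstance(test["p"], float) else "—")
            else:
                tcell = pcell = "—"
            lines.append(f"| {p} | {cells[0]} | {cells[1]} | {tcell} | {pcell} |")
        lines.append("")
    lr = body["survival"].get("log_rank")
    if lr:
        lines.append("## Survival")
        for d in diets:
            ml = body["survival"][d]["mean_lifespan"]
            lines.append(f"- mean lifespan on {d}: {ml:.1f} days")
        lines.append(f"- log-rank chi2 = {lr['statistic']:.2f}, "
                     f"p = {lr['p']:.4f}")
    for diag in body["diagnostics"]:
        lines.append(f"> note: {diag}")
    return "\n".join(lines) + "\n"


def _render_tsv(body, out_dir) -> list[str]:
    diets = body["diets"]
    paths = []
    p1 = os.path.join(out_dir, "traits.tsv")
    with open(p1, "w", encoding="utf-8") as fh:
        fh.write("diet\ttrait\tmean\tse\tn\tunit\n")
        for d in diets:
            for t in body["traits"][d]:
                fh.write(f"{d}\t{t['trait']}\t{t['mean']}\t{t['se']}\t"
                         f"{t['n']}\t{t['unit']}\n")
    paths.append(p1)
    p2 = os.path.join(out_dir, "params.tsv")
    with open(p2, "w", encoding="utf-8") as fh:
        fh.write("diet\tparameter\testimate_all\tjackknife_mean\t"
                 "jackknife_se\tn\n")
        for d in diets:
            for p, jk in body["demography"].get(d, {}).items():
                fh.write(f"{d}\t{p}\t{jk['estimate_all']}\t{jk['mean']}\t"
                         f"{jk['se']}\t{jk['n']}\n")
    paths.append(p2)
    p3 = os.path.join(out_dir, "comparisons.tsv")
    with open(p3, "w", encoding="utf-8") as fh:
        fh.write("comparison\tmethod\tstatistic\tdf\tp\n")
        for section in ("trait_tests", "demography_tests"):
            for name, t in body[section].items():
                fh.write(f"{name}\t{t['method']}\t{t['statistic']}\t"
                         f"{t['df']}\t{t['p']}\n")
        lr = body["survival"].get("log_rank")
        if lr:
            fh.write(f"lifespan\t{lr['method']}\t{lr['statistic']}\t"
                     f"{lr['df']}\t{lr['p']}\n")
    paths.append(p3)
    for d in diets:
        km = body["survival"][d]["km"]
        p4 = os.path.join(out_dir, f"km_{d.replace(' ', '_')}.tsv")
        with open(p4, "w", encoding="utf-8") as fh:
            fh.write("time\tn_risk\tn_event\tsurv\tci_low\tci_high\n")
            for i in range(len(km["times"])):
                fh.write(f"{km['times'][i]}\t{km['n_risk'][i]}\t"
                         f"{km['n_event'][i]}\t{km['surv'][i]}\t"
                         f"{km['ci_low'][i]}\t{km['ci_high'][i]}\n")
        paths.append(p4)
    return paths
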