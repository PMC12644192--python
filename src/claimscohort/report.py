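"""Report writers: CSV outputs, a markdown summary, and a balance plot.

Rounding conventions follow the study-report style: rates and rate ratios
to 2 decimal places, standardized differences to 3, weighted Ns to 1.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .study import StudyReport

__all__ = ["write_report", "format_rates_table", "format_balance_table",
           "plot_standardized_differences"]


def format_rates_table(rates: pd.DataFrame) -> pd.DataFrame:
    out = rates.copy()
    for col in ("value", "ci_low", "ci_high"):
        out[col] = out[col].round(2)
    out["events"] = out["events"].round(1)
    out["person_years"] = out["person_years"].round(1)
    return out


def format_balance_table(balance: pd.DataFrame) -> pd.DataFrame:
    out = balance.copy()
    for col in out.columns:
        if col.startswith(("exposure_", "control_")):
            out[col] = out[col].round(2)
        if col.startswith("d_"):
            out[col] = out[col].round(3)
    return out


def write_report(report: StudyReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the study report as CSV files plus a markdown summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame):
        path = out_dir / name
        df.to_csv(path, index=False)
        written[name] = path

    save("attrition.csv", report.attrition)
    save("cohort.csv", report.cohort.assign(
        index_date=report.cohort["index_date"].dt.strftime("%Y-%m-%d")))
    save("table1_balance.csv", format_balance_table(report.balance))
    save("table2_rates.csv", format_rates_table(report.rates))
    save("propensity_scores.csv", pd.DataFrame({
        "patient_id": report.propensity.ps.index,
        "ps": report.propensity.ps.to_numpy(),
        "weight": report.weights.reindex(report.propensity.ps.index).to_numpy(),
    }))
    save("posthoc_clinical.csv", report.posthoc_clinical)
    save("posthoc_antibacterials.csv", report.posthoc_antibacterial)
    for (definition, adjustment, group), curve in report.km.items():
        save(f"km_{definition}_{adjustment}_{group}.csv", curve)
    for definition, fu in report.followups.items():
        save(f"follow_up_{definition}.csv", fu.assign(
            index_date=fu["index_date"].astype("datetime64[ns]").dt.strftime("%Y-%m-%d"),
            end_date=fu["end_date"].astype("datetime64[ns]").dt.strftime("%Y-%m-%d")))

    md = _markdown_summary(report)
    md_path = out_dir / "report.md"
    md_path.write_text(md, encoding="utf-8")
    written["report.md"] = md_path
    return written


def _markdown_summary(report: StudyReport) -> str:
    n_e = int((report.cohort["group"] == "exposure").sum())
    n_c = int((report.cohort["group"] == "control").sum())
    wn = report.balance.attrs.get("weighted_n", {})
    lines = [
        "# Severe-infection incidence study report",
        "",
        f"Cohort: {n_e} exposure / {n_c} control patients "
        f"(SMRW-weighted N: {wn.get('exposure_adj', float('nan')):.1f} / "
        f"{wn.get('control_adj', float('nan')):.1f}).",
        "",
        "## Attrition",
        report.attrition.to_markdown(index=False),
        "",
        "## Covariate balance (standardized differences)",
        format_balance_table(report.balance)[
            ["covariate", "d_unadj", "d_adj"]].to_markdown(index=False),
        "",
        "## Incidence rates and rate ratios",
        format_rates_table(report.rates).to_markdown(index=False),
        "",
        "## Log",
    ] + [f"- {line}" for line in report.log]
    return "\n".join(lines) + "\n"


def plot_standardized_differences(balance: pd.DataFrame, path: str | Path) -> None:
    """Love plot of |standardized difference| before/after weighting."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.35 * len(balance) + 1.5))
    y = range(len(balance))
    ax.scatter(balance["d_unadj"].abs(), y, label="unadjusted", marker="o")
    ax.scatter(balance["d_adj"].abs(), y, label="SMRW-adjusted", marker="x")
    ax.axvline(0.1, color="grey", linestyle="--", linewidth=0.8)
    ax.set_yticks(list(y))
    ax.set_yticklabels(balance["covariate"])
    ax.set_xlabel("|standardized difference|")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
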