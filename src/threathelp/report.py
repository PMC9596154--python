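"""Human-readable summary of a pipeline run."""

from __future__ import annotations

import pandas as pd


def _fmt_models(models: pd.DataFrame) -> list[str]:
    lines = []
    for roi, group in models.groupby("roi", sort=True):
        lines.append(f"  {roi}")
        for _, row in group.iterrows():
            p_fdr = "  --  " if pd.isna(row.get("p_fdr")) else f"{row['p_fdr']:.4f}"
            lines.append(
                f"    {row['term']:<13s} beta={row['beta']:>9.3f}  "
                f"se={row['se']:>8.3f}  t={row['t']:>7.3f}  "
                f"p={row['p']:.4f}  p_fdr={p_fdr}"
            )
    return lines


def render_report(
    models: pd.DataFrame,
    predominance: pd.DataFrame | None = None,
    classification: pd.Series | None = None,
    config_echo: dict | None = None,
) -> str:
    """Render per-ROI coefficient tables, the FDR-significant list, the
    imminence-preference counts, and the configuration echo as plain text."""
    lines = ["threathelp analysis report", "=" * 26, ""]

    lines.append("Per-ROI linear models of helping % (outcome in percentage points):")
    lines += _fmt_models(models)
    lines.append("")

    sig = models.loc[models.get("significant", False) == True]  # noqa: E712
    if len(sig):
        lines.append("Significant after FDR (adjusted p < alpha):")
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['roi']}: {row['term']} "
                f"(beta={row['beta']:.3f}, p_fdr={row['p_fdr']:.4f})"
            )
    else:
        lines.append("no ROI passed FDR")
    lines.append("")

    if predominance is not None and len(predominance):
        lines.append("Predominance (threat vs distress representation, Wilcoxon):")
        for _, row in predominance.iterrows():
            flag = " *" if row["significant"] else ""
            lines.append(
                f"  {row['roi']:<18s} {row['condition']:<8s} "
                f"mean dtau={row['mean_tau_diff']:>8.4f}  p_fdr={row['p_fdr']:.4f}"
                f"  -> {row['direction']}{flag}"
            )
        lines.append("")

    if classification is not None:
        lines.append("Imminence preference (helping more under imminent vs distal):")
        for name in ("more_imminent", "more_distal", "equal"):
            lines.append(f"  {name:<14s} {int(classification[name])}")
        lines.append("")

    if config_echo is not None:
        lines.append("Configuration:")
        for section, value in config_echo.items():
            lines.append(f"  {section}: {value}")
        lines.append("")

    return "\n".join(lines) + "\n"
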