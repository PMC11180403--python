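"""Plain-text rendering of the trial comparison tables.

Formatting conventions follow the clinical-report style: skewed outcomes as
``median [Q1, Q3]``, symmetric ones as ``mean ± SD``, proportions as
``n (%)``, with the group difference, its 95% CI and the p-value per row.
"""

from __future__ import annotations

from typing import Dict, Mapping

import pandas as pd

_TITLES = {
    "table1": "Table 1. Baseline characteristics",
    "table2": "Table 2. Hypotension burden and clinician behaviour",
    "table3": "Table 3. Treatment-option usage",
    "table4": "Table 4. Safety outcomes",
}


def fmt_median_iqr(median: float, q1: float, q3: float, nd: int = 2) -> str:
    return f"{median:.{nd}f} [{q1:.{nd}f}, {q3:.{nd}f}]"


def fmt_mean_sd(mean: float, sd: float, nd: int = 1) -> str:
    return f"{mean:.{nd}f} ± {sd:.{nd}f}"


def fmt_p(p: float) -> str:
    if pd.isna(p):
        return "-"
    return "< 0.001" if p < 0.001 else f"{p:.3f}" if p < 0.1 else f"{p:.2f}"


def render_table(name: str, df: pd.DataFrame) -> str:
    title = _TITLES.get(name, name)
    lines = [title, "-" * len(title)]
    if df.empty:
        lines.append("(no rows)")
        return "\n".join(lines) + "\n"
    for _, r in df.iterrows():
        est = "-"
        if pd.notna(r.get("estimate")):
            est = f"{r['estimate']:.2f}"
            if pd.notna(r.get("ci_low")) and pd.notna(r.get("ci_high")):
                est += f" ({r['ci_low']:.2f}, {r['ci_high']:.2f})"
        lines.append(f"  {r['outcome']:<42} {str(r['intervention']):>22} "
                     f"{str(r['control']):>22}  diff {est:>24}  p {fmt_p(r['p_value'])}")
    return "\n".join(lines) + "\n"


def render_tables(tables: Mapping[str, pd.DataFrame]) -> str:
    return "\n".join(render_table(name, tables[name]) for name in sorted(tables))
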