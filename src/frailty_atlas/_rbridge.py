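"""Subprocess bridge to lme4::glmer for the crossed-random-intercept logistic fit.

The design matrix, outcome and grouping factors are written to a temporary CSV,
a small R script runs ``glmer`` (binomial family, Laplace approximation,
bobyqa optimiser) and writes fixed effects, random-intercept variances and a
convergence flag back as CSV/text, which are read into Python structures.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["glmer_available", "fit_glmer"]

_R_TEMPLATE = """
options(warn = 1)
suppressMessages(library(lme4))
d <- read.csv("{data}", check.names = FALSE)
d$`__subject` <- factor(d$`__subject`)
d$`__country` <- factor(d$`__country`)
f <- as.formula(paste("`__y` ~ 0 +", paste(sprintf("`%s`", {xcols}), collapse = " + "),
                      "+ (1 | `__subject`) + (1 | `__country`)"))
m <- glmer(f, data = d, family = binomial,
           control = glmerControl(optimizer = "bobyqa", calc.derivs = FALSE))
fe <- fixef(m)
se <- sqrt(diag(as.matrix(vcov(m))))
write.csv(data.frame(term = names(fe), estimate = as.numeric(fe), se = as.numeric(se)),
          "{fixef}", row.names = FALSE)
vc <- as.data.frame(VarCorr(m))
write.csv(vc[, c("grp", "vcov")], "{vc}", row.names = FALSE)
msgs <- m@optinfo$conv$lme4$messages
writeLines(c(ifelse(is.null(msgs), "converged", "not_converged"),
             if (!is.null(msgs)) msgs else character(0)), "{conv}")
"""


def glmer_available() -> bool:
    return shutil.which("Rscript") is not None


def fit_glmer(
    X: pd.DataFrame,
    y: np.ndarray,
    subject: pd.Series,
    country: pd.Series,
    timeout: float = 1800.0,
):
    """Fit the mixed logistic model; returns (params, bse, variances, converged).

    ``params``/``bse`` are pandas Series indexed by the columns of ``X``;
    ``variances`` maps ``subject``/``country`` to random-intercept variances.
    """
    if not glmer_available():
        raise RuntimeError(
            "Rscript/lme4 not available; use backend='ordinary' for a fixed-effects-only fit"
        )
    # R-safe surrogate column names, mapped back on return
    xcols = [f"x{i + 1}" for i in range(X.shape[1])]
    with tempfile.TemporaryDirectory(prefix="frailty_glmm_") as tmp:
        tmp = Path(tmp)
        data = pd.DataFrame(np.asarray(X, dtype=float), columns=xcols)
        data["__y"] = np.asarray(y, dtype=int)
        data["__subject"] = np.asarray(subject).astype(str)
        data["__country"] = np.asarray(country).astype(str)
        data_path = tmp / "data.csv"
        data.to_csv(data_path, index=False)
        xcols_r = "c(" + ", ".join(f'"{c}"' for c in xcols) + ")"
        script = _R_TEMPLATE.format(
            data=data_path.as_posix(),
            xcols=xcols_r,
            fixef=(tmp / "fixef.csv").as_posix(),
            vc=(tmp / "vc.csv").as_posix(),
            conv=(tmp / "conv.txt").as_posix(),
        )
        script_path = tmp / "fit.R"
        script_path.write_text(script)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script_path)],
            capture_output=True,
            text=True,
            timeout=timeout,
        )
        if proc.returncode != 0 or not (tmp / "fixef.csv").exists():
            raise RuntimeError(f"glmer fit failed:\n{proc.stderr[-2000:]}")
        fixef = pd.read_csv(tmp / "fixef.csv")
        vc = pd.read_csv(tmp / "vc.csv")
        conv_lines = (tmp / "conv.txt").read_text().splitlines()
    name_map = dict(zip(xcols, X.columns))
    params = pd.Series(fixef["estimate"].values, index=[name_map[t] for t in fixef["term"]])
    bse = pd.Series(fixef["se"].values, index=params.index)
    params = params.reindex(X.columns)
    bse = bse.reindex(X.columns)
    variances = {}
    for _, row in vc.iterrows():
        grp = str(row["grp"]).replace("__", "")
        variances[grp] = float(row["vcov"])
    converged = bool(conv_lines and conv_lines[0] == "converged")
    return params, bse, variances, converged
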