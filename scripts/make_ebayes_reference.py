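"""Generate the committed moderated-t reference fixture.

Writes a deterministic 200x6 log2 matrix (3 ref vs 3 alt samples) and runs
Bioconductor limma (lmFit + eBayes) on it, freezing t/p/d0/s0 into
tests/data/ for the oracle test.  Run once; outputs are committed.
"""

import subprocess
from pathlib import Path

import numpy as np
import pandas as pd

root = Path(__file__).resolve().parents[1]
out = root / "tests" / "data"
out.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(20240917)
n, per = 200, 3
baseline = rng.uniform(5.0, 10.0, n)
effects = np.zeros(n)
idx = rng.choice(n, 40, replace=False)
effects[idx] = rng.uniform(-2.0, 2.0, 40)
noise = rng.normal(0.0, 0.5, (n, 2 * per))
x = baseline[:, None] + noise
x[:, per:] += effects[:, None]

features = [f"f{i:03d}" for i in range(n)]
cols = [f"ref_{i+1}" for i in range(per)] + [f"alt_{i+1}" for i in range(per)]
df = pd.DataFrame(x, index=features, columns=cols)
matrix_path = out / "ebayes_matrix.tsv"
with open(matrix_path, "w") as fh:
    fh.write("feature\t" + "\t".join(cols) + "\n")
    for fid, row in df.iterrows():
        fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row.to_numpy()) + "\n")

r_code = f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{matrix_path}", row.names=1, check.names=FALSE))
group <- factor(c(rep("ref",{per}), rep("alt",{per})), levels=c("ref","alt"))
design <- model.matrix(~group)
fit <- eBayes(lmFit(x, design))
res <- data.frame(
  feature=rownames(x),
  log2fc=fit$coefficients[,2],
  t=fit$t[,2],
  p=fit$p.value[,2],
  s2_post=fit$s2.post,
  stringsAsFactors=FALSE)
write.table(format(res, digits=17, trim=TRUE, scientific=TRUE),
            "{out}/ebayes_limma_reference.tsv",
            sep="\\t", quote=FALSE, row.names=FALSE)
cat(sprintf("d0=%.17g s0_sq=%.17g df_total=%.17g\\n",
    fit$df.prior, fit$s2.prior, fit$df.total[1]),
    file="{out}/ebayes_limma_hyperparams.txt")
"""
subprocess.run(["Rscript", "-e", r_code], check=True)
print("wrote", matrix_path, "and limma reference")
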