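"""Joint morphospace PCA and site centroids.

Fits one correlation-matrix PCA to all size-corrected specimens (marine and
freshwater together), reports the variance structure, and writes per-site
centroids in PC space.

Writes results/morphospace/{pca_loadings,pca_scores,pca_pct_variance,centroids}.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mfdiv import morphospace


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--corrected", default="results/preprocess/specimens_corrected.csv")
    ap.add_argument("--outdir", default="results/morphospace")
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    corrected = pd.read_csv(args.corrected)

    pca = morphospace.run_pca(corrected)
    centroids = morphospace.site_centroids(pca)

    pca.loadings.to_csv(out / "pca_loadings.csv", float_format="%.12g")
    pca.scores.to_csv(out / "pca_scores.csv", float_format="%.12g")
    pca.pct_variance.to_frame().to_csv(out / "pca_pct_variance.csv", float_format="%.12g")
    centroids.to_csv(out / "centroids.csv", float_format="%.12g")

    v = pca.pct_variance
    print(f"morphospace over {len(pca.scores)} fish, {len(pca.loadings)} traits")
    print(f"  PC1 {v['PC1']:.1f}%  PC2 {v['PC2']:.1f}%  PC3 {v['PC3']:.1f}% of variance")
    top = pca.loadings["PC1"].abs().sort_values(ascending=False).head(4)
    print(f"  strongest PC1 loadings: {', '.join(top.index)}")
    print(f"wrote morphospace tables to {out}/")


if __name__ == "__main__":
    main()
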