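"""NCA feature weighting on the variant-I feature table.

Reads results/features_variant1.csv (built by 03_feature_table.py, which is
invoked if the table is missing), cross-validates the regularization
strength, and writes the per-feature weight table to
results/nca_weights_variant1.csv.
"""

import os
import subprocess
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), os.pardir, "src"))

from vagdx import io as vio
from vagdx.features import FEATURE_NAMES
from vagdx.nca import LabeledDataset, fit_nca

OUT = os.path.join(os.path.dirname(__file__), os.pardir, "results")
FEATURES = os.path.join(OUT, "features_variant1.csv")


def main() -> None:
    if not os.path.exists(FEATURES):
        subprocess.run([sys.executable, os.path.join(
            os.path.dirname(__file__), "03_feature_table.py")], check=True)
    df = vio.read_feature_table(FEATURES)
    ds = LabeledDataset(X=df[FEATURE_NAMES].to_numpy(),
                        y=(df["label"] == "OA").astype(int).to_numpy(),
                        feature_names=list(FEATURE_NAMES))
    model = fit_nca(ds, seed=1)
    table = model.weight_table().sort_values("w_squared", ascending=False)
    table.to_csv(os.path.join(OUT, "nca_weights_variant1.csv"), index=False,
                 float_format="%.6g", lineterminator="\n")
    print(table.to_string(index=False))
    print(f"\nlambda = {model.lam:.3g}, objective = {model.objective:.3f}")
    print("selected:", ", ".join(model.feature_names[i] for i in model.selected))


if __name__ == "__main__":
    main()
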