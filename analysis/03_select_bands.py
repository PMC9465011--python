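"""Select key wavebands: pooled PCA pre-selection, then SFS per classifier.

Runs the full key-wavelength study on the default cohort, writes the SFS
trajectories (selected bands and accuracies at k = 1..5) as JSON, the
chosen key wavelengths per classifier as CSV, and an accuracy-versus-band-
count figure for the four classifiers.
"""

import json
import os
import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from bruisebands import CLASSIFIER_IDS
from bruisebands.workflow import run_key_wavelength_study

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 1


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        study = run_key_wavelength_study(seed=SEED)

    evr = study.pooled.explained_variance_ratio
    print("pooled PCA of extracted spectra: "
          + ", ".join(f"PC{k + 1} {100 * v:.2f}%" for k, v in enumerate(evr)))
    print(f"  cumulative PC1-PC4: {100 * study.cumulative_variance_pc1_4:.2f}%")
    print(f"candidate wavelengths ({study.candidates.pooled_nm.size}): "
          + ", ".join(f"{w:.1f}" for w in study.candidates.pooled_nm))

    traj_json = {}
    rows = []
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True, sharey=True)
    for ax, cid in zip(axes.ravel(), CLASSIFIER_IDS):
        t = study.selection.trajectories[cid]
        traj_json[cid] = {
            "selected_nm": [float(x) for x in t.selected_nm],
            "cv_accuracy": t.cv_accuracy,
            "test_accuracy": t.test_accuracy,
        }
        k = study.selection.optimal_count
        rows.append({"classifier": cid,
                     **{f"wavelength_{j + 1}_nm": t.selected_nm[j]
                        for j in range(k)},
                     "test_accuracy_at_k": t.test_accuracy[k - 1]})
        ks = range(1, len(t.cv_accuracy) + 1)
        ax.plot(ks, [100 * a for a in t.cv_accuracy], "o-", label="5-fold CV")
        ax.plot(ks, [100 * a for a in t.test_accuracy], "s--", label="test")
        ax.set_title(cid)
        ax.set_ylim(60, 100)
        ax.grid(alpha=0.3)
    axes[0, 0].legend()
    for ax in axes[1]:
        ax.set_xlabel("number of selected wavebands")
    for ax in axes[:, 0]:
        ax.set_ylabel("accuracy (%)")
    fig.suptitle("Sequential forward selection over PCA-pre-selected wavebands")
    fig.tight_layout()
    fig.savefig(os.path.join(OUT, "sfs_accuracy_vs_bands.png"), dpi=150)

    with open(os.path.join(OUT, "sfs_trajectories.json"), "w") as fh:
        json.dump(traj_json, fh, indent=2)
    key = pd.DataFrame(rows)
    key.to_csv(os.path.join(OUT, "key_wavelengths.csv"), index=False)

    print(f"optimal number of wavebands (plateau rule): "
          f"{study.selection.optimal_count}"
          + (" (warning: no plateau)" if study.selection.warning else ""))
    print(key.to_string(index=False))
    print(f"wrote trajectories, key wavelengths and figure to {OUT}")


if __name__ == "__main__":
    main()
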