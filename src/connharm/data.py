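"""Dataset container and covariate design for multi-site connectivity studies.

A :class:`ConnectivityDataset` holds the N×V feature table (vectorised
functional-connectivity features) together with the phenotype manifest:
acquisition site, diagnosis (NC=0, SZ=1, unlabelled=-1), age in years and
gender.  The :class:`DesignInfo` encodes the covariate design used by the
location-scale site-effect model: age is z-scored with training-split
statistics, gender is one-hot encoded, and site membership is exposed as an
integer index into the site vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NC, SZ, UNLABELLED = 0, 1, -1
_DIAG_TO_CODE = {"NC": NC, "SZ": SZ, "NA": UNLABELLED, "": UNLABELLED}
_CODE_TO_DIAG = {NC: "NC", SZ: "SZ", UNLABELLED: "NA"}


@dataclass
class ConnectivityDataset:
    """N subjects × V connectivity features plus phenotype columns."""

    features: np.ndarray          # (N, V) float
    subject_id: np.ndarray        # (N,) str
    site: np.ndarray              # (N,) str
    diagnosis: np.ndarray         # (N,) int in {0, 1, -1}
    age: np.ndarray               # (N,) float, years
    gender: np.ndarray            # (N,) str, e.g. "F"/"M"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        n = self.features.shape[0]
        for name in ("subject_id", "site", "diagnosis", "age", "gender"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
            setattr(self, name, arr)
        self.diagnosis = self.diagnosis.astype(int)
        self.age = self.age.astype(float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite values in feature table")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def sites(self) -> list[str]:
        return sorted(set(self.site.tolist()))

    @property
    def labelled_mask(self) -> np.ndarray:
        return self.diagnosis != UNLABELLED

    def subset(self, idx) -> "ConnectivityDataset":
        idx = np.asarray(idx)
        return ConnectivityDataset(
            features=self.features[idx],
            subject_id=self.subject_id[idx],
            site=self.site[idx],
            diagnosis=self.diagnosis[idx],
            age=self.age[idx],
            gender=self.gender[idx],
        )

    # -- IO -------------------------------------------------------------------
    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_id,
            "site": self.site,
            "diagnosis": [_CODE_TO_DIAG[int(d)] for d in self.diagnosis],
            "age": self.age,
            "gender": self.gender,
        })

    def save(self, manifest_path, features_path) -> None:
        self.manifest_frame().to_csv(manifest_path, sep="\t", index=False)
        pd.DataFrame(self.features, index=self.subject_id).to_csv(
            features_path, sep="\t", header=False)

    @classmethod
    def load(cls, manifest_path, features_path) -> "ConnectivityDataset":
        man = pd.read_csv(manifest_path, sep="\t", dtype={"subject_id": str})
        feat = pd.read_csv(features_path, sep="\t", header=None, index_col=0)
        feat.index = feat.index.astype(str)
        feat = feat.loc[man["subject_id"].tolist()]
        diag = man["diagnosis"].fillna("NA").map(
            lambda s: _DIAG_TO_CODE[str(s).strip().upper()]).to_numpy()
        return cls(
            features=feat.to_numpy(dtype=float),
            subject_id=man["subject_id"].to_numpy(dtype=str),
            site=man["site"].to_numpy(dtype=str),
            diagnosis=diag,
            age=man["age"].to_numpy(dtype=float),
            gender=man["gender"].to_numpy(dtype=str),
        )


@dataclass
class DesignInfo:
    """Covariate design fitted on a training split.

    Continuous covariates (age) are z-scored with the training mean/s.d. so
    the learnable covariate coefficients stay on comparable scales; gender is
    one-hot over the training vocabulary; sites index into a fixed vocabulary.
    """

    site_vocab: list[str]
    gender_vocab: list[str]
    age_mean: float
    age_std: float

    @classmethod
    def fit(cls, dataset: ConnectivityDataset) -> "DesignInfo":
        ages = dataset.age
        std = float(np.std(ages))
        return cls(
            site_vocab=sorted(set(dataset.site.tolist())),
            gender_vocab=sorted(set(dataset.gender.tolist())),
            age_mean=float(np.mean(ages)),
            age_std=std if std > 0 else 1.0,
        )

    @property
    def n_covariates(self) -> int:
        return 1 + len(self.gender_vocab)

    @property
    def n_sites(self) -> int:
        return len(self.site_vocab)

    def covariate_matrix(self, dataset: ConnectivityDataset) -> np.ndarray:
        """(N, C) design rows: z-scored age followed by gender one-hot."""
        n = dataset.n_subjects
        M = np.zeros((n, self.n_covariates))
        M[:, 0] = (dataset.age - self.age_mean) / self.age_std
        for k, g in enumerate(self.gender_vocab):
            M[:, 1 + k] = dataset.gender == g
        return M

    def site_index(self, dataset: ConnectivityDataset) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.site_vocab)}
        try:
            return np.array([lut[s] for s in dataset.site], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"unknown site {exc.args[0]!r}; known: {self.site_vocab}")

    def site_onehot(self, dataset: ConnectivityDataset) -> np.ndarray:
        idx = self.site_index(dataset)
        S = np.zeros((len(idx), self.n_sites))
        S[np.arange(len(idx)), idx] = 1.0
        return S
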