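"""Cohort-level stability model and its fitted results.

:class:`RoiStabilityModel` holds the data (a cohort of aligned ADC volume /
ROI mask pairs) and the protocol parameters (discretizations, translation
entities, ICC form, KDE settings).  ``fit()`` runs the whole procedure —
translate every ROI at every entity, extract the 69-feature catalog for the
original and each translated ROI, summarize Diff% and ICC per feature and
entity, derive the KDE-quantile thresholds from the pooled minimal- and
maximal-entity ICCs, and classify each feature — and returns a
:class:`StabilityResults` carrying the records, thresholds, selection table
and summary.

To pool thresholds across several cohorts (the way multiple datasets are
combined into one histogram), use :func:`fit_shared_thresholds`.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .features import BinningSpec, extract_all
from .features.catalog import ALL_FEATURE_NAMES
from .perturb import DEFAULT_ENTITIES, translate_mask, translation_suite
from .phantom import CohortVariation, PhantomSpec, generate_cohort
from .stability import (
    ORIGINAL_ID,
    StabilityRecord,
    ThresholdPair,
    classify_features,
    derive_thresholds,
    summarize,
)
from .volume import ImageVolume, RoiMask

DEFAULT_BINNINGS = (16, 32, 64)


class RoiStabilityModel:
    """Radiomic feature stability model for one cohort.

    Parameters
    ----------
    volumes, masks : sequences of aligned :class:`ImageVolume` /
        :class:`RoiMask` pairs, one per subject (>= 2 subjects).
    binnings : bin counts of the histogram discretizations (default 16/32/64).
    entities : translation entities as bounding-box fractions
        (default 0.1 ... 1.0, step 0.1).
    icc_form : "consistency" (default) or "agreement".
    kde_bandwidth, quantile_low, quantile_high : threshold-derivation
        settings (defaults 0.05, 0.1, 0.9).
    feature_classes : subset of ("fos", "glcm", "glrlm") to extract.
    """

    def __init__(
        self,
        volumes,
        masks,
        binnings=DEFAULT_BINNINGS,
        entities=DEFAULT_ENTITIES,
        icc_form: str = "consistency",
        kde_bandwidth: float = 0.05,
        quantile_low: float = 0.1,
        quantile_high: float = 0.9,
        feature_classes: tuple[str, ...] = ("fos", "glcm", "glrlm"),
    ):
        volumes = list(volumes)
        masks = list(masks)
        if len(volumes) != len(masks):
            raise ValueError("one mask per volume required")
        if len(volumes) < 2:
            raise ValueError("stability analysis needs at least 2 subjects")
        for i, (v, m) in enumerate(zip(volumes, masks)):
            if not m.same_grid(v):
                raise ValueError(f"subject {i}: mask and volume grids differ")
        self.volumes = volumes
        self.masks = masks
        self.binnings = tuple(int(b) for b in binnings)
        self.entities = tuple(sorted(float(e) for e in entities))
        if not self.entities:
            raise ValueError("at least one translation entity required")
        self.icc_form = icc_form
        self.kde_bandwidth = float(kde_bandwidth)
        self.quantile_low = float(quantile_low)
        self.quantile_high = float(quantile_high)
        self.feature_classes = tuple(feature_classes)
        self._feature_table: pd.DataFrame | None = None

    @classmethod
    def from_phantom_cohort(
        cls,
        n_subjects: int = 18,
        spec: PhantomSpec = PhantomSpec(),
        variation: CohortVariation = CohortVariation(),
        seed: int = 0,
        **kwargs,
    ) -> "RoiStabilityModel":
        """Build the model on a synthetic phantom cohort."""
        cohort = generate_cohort(n_subjects, spec, variation, seed)
        vols, msks = zip(*cohort)
        return cls(vols, msks, **kwargs)

    @property
    def n_subjects(self) -> int:
        return len(self.volumes)

    def extract_features(self) -> pd.DataFrame:
        """Tidy feature table over subjects, binnings and transforms.

        Columns: ``subject_id, binning, feature_name, value, transform_id``
        where ``transform_id`` is "original" or e.g. "t010+x" (entity 10%,
        positive x shift).  Cached after the first call.
        """
        if self._feature_table is not None:
            return self._feature_table
        binnings = [BinningSpec(b) for b in self.binnings]
        rows = []

        def add(subject_id, transform_id, volume, mask):
            per_binning = extract_all(volume, mask, binnings, classes=self.feature_classes)
            for n_bins, feats in per_binning.items():
                for name, value in feats.items():
                    rows.append((subject_id, n_bins, name, value, transform_id))

        for i, (vol, mask) in enumerate(zip(self.volumes, self.masks)):
            sid = f"subject_{i:03d}"
            add(sid, ORIGINAL_ID, vol, mask)
            for spec in translation_suite(mask, self.entities):
                add(sid, spec.transform_id, vol, translate_mask(mask, spec))
        self._feature_table = pd.DataFrame(
            rows, columns=["subject_id", "binning", "feature_name", "value", "transform_id"]
        )
        return self._feature_table

    def fit(self, thresholds: ThresholdPair | None = None) -> "StabilityResults":
        """Run the full stability and discrimination analysis.

        If *thresholds* is given (e.g. pooled across cohorts) it is used
        directly; otherwise thresholds are derived from this cohort's own
        pooled minimal/maximal-entity ICC_mean values.
        """
        table = self.extract_features()
        records: list[StabilityRecord] = []
        for binning in self.binnings:
            for entity in self.entities:
                records.extend(summarize(table, entity, binning, icc_form=self.icc_form))
        e_min, e_max = self.entities[0], self.entities[-1]
        pool10 = [r.icc_mean for r in records if r.entity == e_min]
        pool100 = [r.icc_mean for r in records if r.entity == e_max]
        if thresholds is None:
            thresholds = derive_thresholds(
                pool10, pool100, self.kde_bandwidth, self.quantile_low, self.quantile_high
            )
        selection = classify_features(
            [r for r in records if r.entity == e_min],
            [r for r in records if r.entity == e_max],
            thresholds,
        )
        return StabilityResults(self, table, records, thresholds, selection)


class StabilityResults:
    """Fitted output of :class:`RoiStabilityModel`.

    Attributes
    ----------
    feature_table : tidy per-subject feature values for every transform.
    records : list of :class:`StabilityRecord` over features x binnings x
        entities.
    thresholds : the :class:`ThresholdPair` used for classification.
    selection : DataFrame ``feature_name, binning, icc_10, icc_100, label``.
    """

    def __init__(self, model, feature_table, records, thresholds, selection):
        self.model = model
        self.feature_table = feature_table
        self.records = records
        self.thresholds = thresholds
        self.selection = selection

    @property
    def records_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "feature_name": r.feature_name,
                    "binning": r.binning,
                    "entity": r.entity,
                    "icc_mean": r.icc_mean,
                    "icc_ci_low": r.icc_ci95[0],
                    "icc_ci_high": r.icc_ci95[1],
                    "diffpct_mean": r.diffpct_mean,
                    "diffpct_ci_low": r.diffpct_ci95[0],
                    "diffpct_ci_high": r.diffpct_ci95[1],
                    "n_diffpct": r.n_diffpct,
                    "n_excluded": r.n_excluded,
                }
            )
        return pd.DataFrame(rows)

    def heatmap(self, binning: int, quantity: str = "icc_mean") -> pd.DataFrame:
        """Features x entities matrix of ICC_mean (or diffpct_mean) for one binning."""
        df = self.records_frame
        df = df[df["binning"] == binning]
        mat = df.pivot(index="feature_name", columns="entity", values=quantity)
        order = [n for n in ALL_FEATURE_NAMES if n in mat.index]
        return mat.loc[order]

    def excluded(self, binning: int) -> set[str]:
        """Names of features not selected (unstable or non-discriminative)."""
        sel = self.selection
        sub = sel[(sel["binning"] == binning) & (sel["label"] != "selected")]
        return set(sub["feature_name"])

    def selected(self, binning: int) -> set[str]:
        sel = self.selection
        sub = sel[(sel["binning"] == binning) & (sel["label"] == "selected")]
        return set(sub["feature_name"])

    def summary(self) -> str:
        """Plain-text summary table of thresholds and per-binning label counts."""
        lines = [
            "Radiomic feature stability analysis",
            "=" * 51,
            f"subjects:            {self.model.n_subjects}",
            f"entities:            {', '.join(f'{e:.1f}' for e in self.model.entities)}",
            f"ICC form:            {self.model.icc_form}",
            f"KDE bandwidth:       {self.thresholds.kde_bandwidth:g}",
            f"ICC_min (Q{self.thresholds.quantile_low:g} of ICC_10 pool, n={self.thresholds.n_pool_low}): "
            f"{self.thresholds.icc_min:.4f}",
            f"ICC_max (Q{self.thresholds.quantile_high:g} of ICC_100 pool, n={self.thresholds.n_pool_high}): "
            f"{self.thresholds.icc_max:.4f}",
            "-" * 51,
            f"{'bins':>6} {'selected':>9} {'unstable':>9} {'non-disc.':>10} {'undefined':>10}",
        ]
        for binning in self.model.binnings:
            sub = self.selection[self.selection["binning"] == binning]
            counts = sub["label"].value_counts()
            lines.append(
                f"{binning:>6} {counts.get('selected', 0):>9} {counts.get('unstable', 0):>9} "
                f"{counts.get('non_discriminative', 0):>10} {counts.get('undefined', 0):>10}"
            )
        lines.append("=" * 51)
        return "\n".join(lines)

    def to_csv(self, out_dir) -> dict[str, str]:
        """Write the tabular outputs; returns a name -> path map."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = {}

        def write(name, df):
            path = out_dir / name
            df.to_csv(path, index=True)
            written[name] = str(path)

        feats = self.feature_table.sort_values(
            ["subject_id", "binning", "feature_name", "transform_id"]
        ).reset_index(drop=True)
        feats.to_csv(out_dir / "features.csv", index=False)
        written["features.csv"] = str(out_dir / "features.csv")
        rec = self.records_frame.sort_values(["binning", "feature_name", "entity"]).reset_index(drop=True)
        rec.to_csv(out_dir / "stability_records.csv", index=False)
        written["stability_records.csv"] = str(out_dir / "stability_records.csv")
        for binning in self.model.binnings:
            write(f"icc_heatmap_bins{binning}.csv", self.heatmap(binning, "icc_mean"))
            write(f"diffpct_heatmap_bins{binning}.csv", self.heatmap(binning, "diffpct_mean"))
        sel = self.selection.sort_values(["binning", "feature_name"]).reset_index(drop=True)
        sel.to_csv(out_dir / "selection.csv", index=False)
        written["selection.csv"] = str(out_dir / "selection.csv")
        report = {
            "thresholds": asdict(self.thresholds),
            "binnings": list(self.model.binnings),
            "entities": list(self.model.entities),
            "icc_form": self.model.icc_form,
            "n_subjects": self.model.n_subjects,
            "labels": {
                str(binning): self.selection[self.selection["binning"] == binning]
                .set_index("feature_name")["label"]
                .to_dict()
                for binning in self.model.binnings
            },
        }
        path = out_dir / "selection.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        written["selection.json"] = str(path)
        return written


def fit_shared_thresholds(models: list[RoiStabilityModel]) -> list[StabilityResults]:
    """Fit several cohorts with thresholds derived from their pooled ICCs.

    The minimal- and maximal-entity ICC_mean values of all cohorts (across
    all discretizations and features) are pooled into single histograms
    before the KDE-quantile thresholds are derived; every cohort is then
    classified against the shared pair.
    """
    if not models:
        raise ValueError("at least one model required")
    pools10, pools100 = [], []
    prelim = []
    for m in models:
        table = m.extract_features()
        records = []
        for binning in m.binnings:
            for entity in (m.entities[0], m.entities[-1]):
                records.extend(summarize(table, entity, binning, icc_form=m.icc_form))
        prelim.append(records)
        pools10 += [r.icc_mean for r in records if r.entity == m.entities[0]]
        pools100 += [r.icc_mean for r in records if r.entity == m.entities[-1]]
    ref = models[0]
    thresholds = derive_thresholds(
        pools10, pools100, ref.kde_bandwidth, ref.quantile_low, ref.quantile_high
    )
    return [m.fit(thresholds=thresholds) for m in models]
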