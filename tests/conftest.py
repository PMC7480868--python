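import numpy as np
import pytest
from hypothesis import settings

from wavesweep import (
    FixtureSpec,
    build_layout,
    featurize,
    filter_minor_allele_count,
    fit_classifier,
    generate_feature_fixtures,
    generate_haplotypes,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


SEPARABLE_CLASSES = {
    "neutral": FixtureSpec(pattern="flat", noise_sd=0.05, trough_width=3.0),
    "sweep": FixtureSpec(
        pattern="trough", trough_depth=0.8, trough_width=3.0, noise_sd=0.05
    ),
}


@pytest.fixture(scope="session")
def default_layout():
    return build_layout()


@pytest.fixture(scope="session")
def separable_train():
    """30 observations per class of well-separated p=16 curve fixtures."""
    feats, labels, _ = generate_feature_fixtures(
        SEPARABLE_CLASSES, n_per_class=30, p=16, seed=11
    )
    return feats, labels


@pytest.fixture(scope="session")
def separable_test():
    feats, labels, _ = generate_feature_fixtures(
        SEPARABLE_CLASSES, n_per_class=40, p=16, seed=99
    )
    return feats, labels


@pytest.fixture(scope="session")
def trained_classifier(separable_train):
    feats, labels = separable_train
    return fit_classifier(
        feats, labels,
        gamma_grid=(0.0, 1.0), level_grid=(0, 2),
        folds=5, seed=1, n_lambda=8,
    )


@pytest.fixture(scope="session")
def trough_region():
    """A MAC-filtered 645-SNP haplotype region with a centered sweep trough."""
    h = generate_haplotypes(
        FixtureSpec(pattern="trough", n_snps=645, seed=21, noise_sd=0.02)
    )
    return filter_minor_allele_count(h)


@pytest.fixture(scope="session")
def haplotype_classifier(default_layout):
    """Classifier trained on haplotype-derived 9x128 feature curves."""
    feats, labels = [], []
    for i in range(12):
        for pattern, label in (("flat", "neutral"), ("trough", "sweep")):
            h = filter_minor_allele_count(generate_haplotypes(
                FixtureSpec(pattern=pattern, n_snps=645, seed=1000 + 7 * i,
                            noise_sd=0.02)
            ))
            feats.append(featurize(h, default_layout, obs_id=f"{label}_{i}"))
            labels.append(label)
    return fit_classifier(
        feats, labels, gamma_grid=(0.0,), level_grid=(3,),
        folds=5, seed=2, n_lambda=6,
    )
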