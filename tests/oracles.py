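"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's code paths: projectors come from
normal equations rather than QR, the Fisher filter from a dense
eigendecomposition of inv(Sw + eps I) @ Sb rather than a generalized
symmetric solver, scatter matrices and correlations from explicit loops.
"""

import numpy as np


def band_power(segment: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Rectangular-window band power: summed squared FFT magnitudes over the
    band, normalized by the squared segment length."""
    spec = np.fft.rfft(segment)
    freqs = np.fft.rfftfreq(len(segment), 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float((np.abs(spec[sel]) ** 2).sum() / len(segment) ** 2)


def _references(freqs, fs, n_p):
    t = np.arange(1, n_p + 1) / fs
    refs = {}
    for i, f in enumerate(freqs, start=1):
        refs[i] = np.array(
            [
                np.sin(2 * np.pi * f * t),
                np.cos(2 * np.pi * f * t),
                np.sin(4 * np.pi * f * t),
                np.cos(4 * np.pi * f * t),
            ]
        )
    return refs


def _projectors(refs):
    return {i: y.T @ np.linalg.inv(y @ y.T) @ y for i, y in refs.items()}


def _augment(x, p):
    return np.hstack([x, x @ p])


def _pearson(a, b):
    a = a.ravel()
    b = b.ravel()
    am, bm = a - a.mean(), b - b.mean()
    na = np.sqrt((am ** 2).sum())
    nb = np.sqrt((bm ** 2).sum())
    if na == 0 or nb == 0:
        return 0.0
    return float((am * bm).sum() / (na * nb))


def tdca_bruteforce_predict(train_x, train_y, test_x, freqs, fs, n_components=4):
    """Labels for test trials via a from-scratch TDCA implementation."""
    n_p = train_x[0].shape[1]
    refs = _references(freqs, fs, n_p)
    proj = _projectors(refs)
    classes = sorted(refs)

    aug = {c: [_augment(x, proj[c]) for x, y in zip(train_x, train_y) if y == c]
           for c in classes}
    means = {c: np.mean(aug[c], axis=0) for c in classes}
    grand = np.mean([means[c] for c in classes], axis=0)
    dim = grand.shape[0]

    s_b = np.zeros((dim, dim))
    s_w = np.zeros((dim, dim))
    for c in classes:
        d = means[c] - grand
        s_b += d @ d.T
        for a in aug[c]:
            r = a - means[c]
            s_w += r @ r.T

    eps = 1e-6 * np.trace(s_w) / dim
    m = np.linalg.inv(s_w + eps * np.eye(dim)) @ s_b
    evals, evecs = np.linalg.eig(m)
    order = np.argsort(evals.real)[::-1]
    k = min(n_components, dim)
    w = np.real(evecs[:, order[:k]])
    w = w / np.sqrt((w ** 2).sum(axis=0, keepdims=True))
    for j in range(w.shape[1]):
        lead = w[np.argmax(np.abs(w[:, j])), j]
        if lead < 0:
            w[:, j] = -w[:, j]

    templates = {c: w.T @ means[c] for c in classes}
    labels = []
    for x in test_x:
        rho = [_pearson(w.T @ _augment(x, proj[c]), templates[c]) for c in classes]
        labels.append(classes[int(np.argmax(rho))])
    return np.array(labels)
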