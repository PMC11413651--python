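"""The four training losses and the chance-level bound.

The harmonization procedure optimizes three losses per batch — disease
binary cross-entropy, scanner categorical cross-entropy, and the
adversarial confusion loss (cross-entropy against the uniform
distribution) — and logs their sum.  The confusion loss can never drop
below ln M and reaches that bound exactly when the scanner head is at
chance, which is the operating point harmonization drives the encoder to.
"""

import numpy as np

from harmonytm import (loss_confusion, loss_pd, loss_scanner, loss_total,
                       one_hot)

y = [1, 0, 1, 1, 0]
p = [0.8, 0.3, 0.6, 0.9, 0.2]
l_pd = loss_pd(y, p)
print(f"disease BCE on a 5-sample batch:            {l_pd:.4f}")

m = 23
Y = one_hot([0, 5, 12], m)
P_sharp = np.full((3, m), 0.01 / (m - 1))
P_sharp[np.arange(3), [0, 5, 12]] = 0.99
l_sc = loss_scanner(Y, P_sharp)
print(f"scanner CCE with confident predictions:     {l_sc:.4f}")

P_uniform = np.full((3, m), 1.0 / m)
l_conf = loss_confusion(P_uniform)
print(f"confusion loss at uniform output:           {l_conf:.4f}"
      f"  (ln {m} = {np.log(m):.4f})")
print(f"confusion loss at the confident output:     "
      f"{loss_confusion(P_sharp):.4f}  (> ln {m}: information remains)")

print(f"total logged loss:                          "
      f"{loss_total(l_pd, l_sc, l_conf):.4f}")
print("A harmonized encoder keeps the first number low while the scanner "
      "head can do no better than the ln M bound.")
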