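"""Train the Logical-SVM-RF cascade on a synthetic cohort and evaluate it.

Generates 10 sessions per MAS grade, extracts fast-stretch features,
splits 90:10 (stratified), trains the cascade on the MAS-4-free training
rows and prints the held-out confusion matrix and metric summary.
"""

from masgrade import dataset as ds
from masgrade.evaluate import evaluate_predictions
from masgrade.models import train_cascade
from masgrade.pipeline import cohort_feature_table, predict_table
from masgrade.synthetic import generate_cohort

recordings, _, _ = generate_cohort(10, seed=7)
table = cohort_feature_table(recordings)
fast = ds.select_fast(table)

train, test = ds.stratified_split(fast, test_frac=0.1, seed=7)
model = train_cascade(ds.exclude_mas4(train), seed=7)

pred = predict_table(model, test)
report = evaluate_predictions(pred["mas_label"], pred["predicted_mas"])
print("confusion matrix (rows = true grade, columns = predicted):")
print(report.confusion_frame().to_string())
print(f"\naccuracy {report.accuracy:.3f}, balanced accuracy {report.balanced_accuracy:.3f}")
print(
    "\nMAS 4 rows never enter classifier training: their near-zero range "
    "of motion triggers the <10 degree rule, so the cascade still grades "
    "them correctly while the five-class SVM/RF handle the other grades."
)
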