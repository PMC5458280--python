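name,K,k,printed_ratio,printed_p_adj
Pathways in cancer,326,43,27.88,4.48e-47
Colorectal cancer,62,17,57.97,3.03e-24
Small cell lung cancer,85,16,39.79,4.45e-20
Prostate cancer,89,16,38.01,8.42e-20
Chronic myeloid leukemia,73,14,40.54,6.77e-18
Pancreatic cancer,70,13,39.26,1.52e-16
Bladder cancer,42,9,45.30,2.41e-12
Non-small cell lung cancer,54,9,35.23,1.98e-11
Hematopoietic cell lineage,88,10,24.02,6.02e-11
Glioma,65,9,29.27,1.00e-10
Melanoma,71,9,26.80,2.09e-10
Renal cell carcinoma,70,8,24.16,4.87e-09
Acute myeloid leukemia,57,7,25.96,2.81e-08
Thyroid cancer,29,3,21.87,5e-04
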