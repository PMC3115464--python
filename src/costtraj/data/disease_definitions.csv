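disease,name,pattern,sex_restriction
achd,Acute coronary heart disease,410.xx,
achd,Acute coronary heart disease,411.xx,
achd,Acute coronary heart disease,413.xx,
stroke,Stroke,431.xx,
stroke,Stroke,433.x1,
stroke,Stroke,434.x1,
stroke,Stroke,436.xx,
ulcer,Ulcer,531.xx,
ulcer,Ulcer,532.xx,
ulcer,Ulcer,533.xx,
ulcer,Ulcer,534.xx,
breast_cancer,Breast cancer,174.xx,female
prostate_cancer,Prostate cancer,185.xx,male
melanoma,Melanoma,172.xx,
lung_cancer,Lung cancer,162.xx,
colon_cancer,Colon cancer,153.xx,
diabetes,Diabetes,250.xx,
asthma,Asthma,493.xx,
parkinsons,Parkinson's disease,332.xx,
alzheimers,Alzheimer's disease,331.0,
alzheimers,Alzheimer's disease,290.1,
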