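feature,random_forest,svm,knn,naive_bayes
Mean (Left Knee),Used,Removed,Removed,Used
Standard Deviation (Left Knee),Used,Used,Removed,Used
Median Absolute Deviation (Left Knee),Removed,Used,Used,Used
Minimum (Left Knee),Used,Used,Used,Used
Maximum (Left Knee),Used,Removed,Used,Removed
Energy Measure (Left Knee),Used,Used,Used,Used
Inter Quartile Range (Left Knee),Used,Used,Used,Removed
Signal Magnitude Area (Left Knee),Used,Used,Removed,Removed
Skewness (Left Knee),Removed,Removed,Used,Used
Kurtosis (Left Knee),Used,Used,Used,Removed
Step Length (Left Knee),Used,Used,Removed,Used
Stride Length (Left Knee),Removed,Removed,Used,Used
Step Time (Left Knee),Used,Removed,Removed,Used
Stride Time (Left Knee),Removed,Used,Used,Used
Step Velocity (Left Knee),Used,Used,Removed,Used
Stride Velocity (Left Knee),Used,Removed,Used,Used
Mean (Right Knee),Used,Used,Removed,Removed
Standard Deviation (Right Knee),Used,Used,Used,Used
Median Absolute Deviation (Right Knee),Used,Used,Used,Used
Minimum (Right Knee),Removed,Removed,Used,Used
Maximum (Right Knee),Used,Used,Used,Removed
Energy Measure (Right Knee),Used,Removed,Used,Used
Inter Quartile Range (Right Knee),Removed,Used,Removed,Removed
Signal Magnitude Area (Right Knee),Used,Removed,Used,Used
Skewness (Right Knee),Used,Used,Used,Used
Kurtosis (Right Knee),Removed,Used,Used,Used
Step Length (Right Knee),Used,Used,Removed,Removed
Stride Length (Right Knee),Removed,Used,Used,Used
Step Time (Right Knee),Used,Removed,Removed,Removed
Stride Time (Right Knee),Removed,Used,Used,Removed
Step Velocity (Right Knee),Used,Removed,Removed,Used
Stride Velocity (Right Knee),Removed,Used,Used,Removed
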