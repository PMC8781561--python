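patient,cough,fever,breathing_issues,chest_pain,loss_of_appetite,energy,fatigue,unnamed,vomiting,nausea,sweating,shaking_chill,diarrhea,label
P-1,0,0,1,1,1,0,0,0,0,0,0,0,0,Normal
P-2,1,0,1,0,0,1,0,0,0,0,0,0,0,Normal
P-3,0,0,0,0,1,0,0,1,0,1,0,0,0,Normal
P-4,1,0,0,1,0,0,1,1,0,1,0,1,0,Normal
P-5,1,0,1,0,0,0,0,0,0,0,0,1,0,Normal
P-6,1,0,1,0,0,1,1,1,0,0,0,0,0,Normal
P-7,1,0,1,0,0,1,1,0,0,0,0,0,0,Normal
P-8,1,0,1,0,1,0,1,1,0,1,0,0,0,Normal
P-9,1,0,1,0,1,0,0,0,0,1,0,0,0,Normal
P-10,1,1,1,0,1,1,1,1,0,0,1,1,0,Normal
P-11,1,0,1,0,1,0,1,1,0,0,1,1,0,Normal
P-12,1,0,1,0,1,0,1,1,0,0,1,0,0,Normal
P-13,1,1,1,0,1,0,0,0,0,0,1,0,0,Normal
P-14,1,1,1,0,1,0,1,1,0,1,1,0,0,Normal
P-15,1,1,0,0,0,1,1,1,0,1,1,0,0,Normal
P-16,0,1,0,0,0,0,0,0,0,0,1,1,0,Normal
P-17,0,1,0,0,0,0,0,0,1,0,1,1,0,Normal
P-18,0,1,0,0,0,0,0,1,0,0,1,1,0,Normal
P-19,0,1,0,1,1,0,0,1,0,0,1,1,0,Normal
P-20,0,1,0,1,0,1,0,1,0,0,1,1,0,Normal
P-21,1,0,1,0,0,0,0,0,0,1,1,0,1,Normal
P-22,1,0,1,0,0,0,0,0,0,1,0,0,0,Normal
P-23,1,0,1,0,0,0,0,0,0,0,0,0,0,Normal
P-24,1,1,0,1,1,0,1,1,1,0,0,1,1,Normal
P-25,1,1,0,1,1,1,1,1,0,0,0,1,1,Normal
P-26,1,1,0,1,1,0,1,1,0,0,0,1,0,Normal
P-27,1,1,1,0,1,0,2,1,0,0,0,0,0,Normal
P-28,0,0,1,0,0,0,2,0,0,0,0,0,0,Normal
P-29,0,1,1,0,0,1,2,0,0,0,0,0,0,Normal
P-30,0,1,1,0,1,0,2,0,0,0,0,0,0,Normal
P-31,0,1,1,0,0,0,2,0,0,0,0,0,0,Pneumonia
P-32,0,1,1,0,1,1,1,0,0,0,1,0,1,Pneumonia
P-33,0,0,1,0,0,1,1,0,0,0,1,0,0,Pneumonia
P-34,1,0,1,0,1,1,1,0,0,0,1,0,0,Pneumonia
P-35,1,0,1,0,0,0,1,0,0,0,1,0,1,Pneumonia
P-36,1,0,1,0,2,0,2,0,0,0,1,1,0,Pneumonia
P-37,1,1,1,0,0,1,1,1,0,0,0,1,1,Pneumonia
P-38,1,0,1,0,1,1,2,1,0,1,0,0,0,Pneumonia
P-39,1,1,1,0,0,0,1,1,0,1,0,1,1,Pneumonia
P-40,1,2,1,0,2,1,0,0,0,1,0,1,0,Pneumonia
P-41,2,2,1,1,2,1,0,0,0,1,1,1,1,Pneumonia
P-42,2,0,0,1,2,0,0,0,0,0,0,0,0,Pneumonia
P-43,2,1,0,0,0,1,0,0,1,1,1,0,1,Pneumonia
P-44,2,0,0,1,1,1,0,0,1,1,0,0,0,Pneumonia
P-45,1,2,0,0,1,1,0,0,1,0,0,0,1,Pneumonia
P-46,1,1,1,1,2,0,1,0,1,1,0,1,1,Pneumonia
P-47,1,2,1,0,2,1,0,0,0,0,1,0,1,Pneumonia
P-48,0,2,1,1,0,1,1,0,0,1,1,1,1,Pneumonia
P-49,2,0,1,0,0,0,1,1,0,1,0,0,1,Pneumonia
P-50,1,0,0,1,0,1,1,0,0,0,0,1,0,Pneumonia
P-51,1,2,0,1,2,1,1,1,2,1,2,1,2,Pneumonia
P-52,1,1,0,1,1,1,2,2,1,1,1,1,1,Pneumonia
P-53,1,1,0,0,2,0,1,2,1,1,2,2,2,Pneumonia
P-54,1,1,0,1,2,1,2,2,1,1,1,2,2,Pneumonia
P-55,1,1,0,0,2,1,2,1,1,1,1,1,1,Pneumonia
P-56,1,1,0,1,2,1,2,2,2,2,2,1,2,Pneumonia
P-57,1,1,0,0,2,0,1,2,2,2,2,2,2,Pneumonia
P-58,1,1,0,0,2,1,1,1,2,2,2,2,2,Pneumonia
P-59,1,1,0,0,2,0,2,2,1,2,2,1,2,Pneumonia
P-60,1,1,0,0,2,1,2,1,2,2,1,2,2,Pneumonia
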