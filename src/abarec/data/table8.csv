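Participant,Age in months,Gender,Domain code recommendation,Target code recommendation,Percentage of relevant domain code,Percentage of relevant target code
Participant 1,50.4,Male,"1, 2, 3, 4, 5, 14","2.1, 2.3, 2.4, 3.2, 3.4, 14.3",87.5,88.3
Participant 2,60,Male,"2, 4, 5, 6","2.1, 2.2, 2.3, 2.4, 5.1, 5.13, 5.2, 5.8, 6.1, 6.11, 6.14, 11.1, 14.1, 14.3",88.0,77.6
Participant 3,60,Male,"1, 2, 4, 7","1.1, 1.2, 1.3, 2.1, 2.4, 2.3, 7.12, 7.19",89.2,87.3
Participant 4,72,Male,"2, 4, 14, 20, 21","2.2, 2.3, 2.4, 4.2, 4.7, 20.3, 21.02",77.5,78.9
Participant 5,48,Male,"1, 2, 4, 14","1.5, 1.6, 1.7, 2.1, 2.3, 4.1, 4.2, 14.1, 14.3",94.4,82.4
Participant 6,57.6,Male,"1, 5, 6","1.3, 5.4, 6.2",73.0,88.4
Participant 7,66,Female,"4, 5, 11","4.1, 4.2, 11.1, 11.2, 11.3",73.7,79.4
Participant 8,55.2,Female,"2, 4, 5","2.1, 2.2, 4.2, 4.5, 5.1, 5.4",91.2,86.4
Participant 9,31.2,Male,"4","4.1, 4.2, 4.4",72.3,81.0
Participant 10,57.6,Male,"1, 4, 5, 17","1.1, 1.2, 4.2, 4.3, 4.4, 5.1, 5.2, 17.2",84.2,87.2
Participant 11,45.6,Male,"1, 2, 4, 5, 11","1.1, 2.1, 4.2, 5.1, 5.4, 11.1, 11.2",85.9,77.4
Participant 12,50.4,Male,"2, 4, 6","2.1, 4.2, 6.21, 6.3, 6.6",95.2,87.0
Participant 13,54,Male,"2, 4","2.1, 4.1, 4.2",70.4,88.8
Participant 14,46.8,Male,"1, 5, 11, 20","1.1, 1.3, 5.1, 5.2, 11.1, 11.2, 11.3, 20.1, 20.5",75.5,82.4
Participant 15,49.2,Male,"4, 9","4.2, 4.3, 9.1, 9.2, 9.4",77.1,76.4
Participant 16,49.3,Male,"1, 2, 4, 5","1.1, 1.3, 2.1, 2.3, 5.1, 5.2",88.2,83.6
Participant 17,33.6,Male,"1, 4, 6","1.2, 1.4, 1.5, 4.1, 4.5, 6.1",86.0,74.4
Participant 18,62.4,Male,"2, 4","2.1, 2.3, 2.4, 4.1, 4.3, 4.5",82.5,84.3
Participant 19,45.6,Female,"2, 4, 6","2.2, 2.3, 4.1, 4.2, 6.2",76.6,71.0
Participant 20,37.2,Male,"1, 2, 4, 5","1.1, 1.2, 4.1, 5.1",85.5,88.7
Participant 21,40.8,Male,"1, 2, 4, 5, 6","1.2, 1.4, 1.5, 4.2, 5.1, 6.22, 6.25",83.1,85.6
Participant 22,48,Male,"1, 4, 5, 7","1.2, 1.3, 4.2, 4.4, 5.1, 5.2, 7.1",77.3,82.4
Participant 23,27.6,Male,"3, 4, 5","3.1, 4.2, 4.4, 5.1, 5.2",73.7,85.8
Participant 24,55.2,Male,"1, 2, 4, 5, 6, 14","1.2, 1.3, 1.5, 1.6, 2.2, 2.3, 4.2, 4.7, 5.1, 5.4, 6.1",79.4,88.2
Participant 25,54,Male,"1, 4, 5","1.3, 4.1, 4.2, 5.2, 5.4",88.5,72.4
Participant 26,62.4,Male,"1, 2, 4","1.1, 2.1, 2.3, 4.3, 4.4",80.7,82.5
Participant 27,48,Male,"7, 14","7.1, 14.2",68.3,75.2
Participant 28,26.4,Male,"1, 4, 5","1.2, 1.4, 4.1, 4.3, 5.1, 5.2",83.4,81.0
Participant 29,56.4,Male,"1, 2, 4, 5","1.1, 1.3, 2.2, 2.4, 5.1, 5.2",85.5,83.5
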