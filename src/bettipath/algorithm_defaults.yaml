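# Pinned "default" hyperparameters for the eight classifiers, versioned here
# so that the meaning of "library defaults" cannot drift across library
# upgrades.  Keys are the fixed algorithm ids.
#
# Deviations from upstream defaults are deliberate and minimal:
#   1: LogisticRegression max_iter raised to 1000 (the upstream default of
#      100 does not converge on several-hundred-column standardized tables).
#   3/4: SVC max_iter bounded at 100000 instead of unlimited — libsvm can
#      fail to terminate on unstandardized features spanning many orders of
#      magnitude, and half the search grid runs without standardization.
#   7: XGBClassifier pinned to 100 trees / logloss eval metric, matching the
#      upstream defaults at the versions this package targets.
algorithms:
  0:
    name: perceptron
    class: sklearn.linear_model.Perceptron
    stochastic: true
    params: {}
  1:
    name: logistic_regression
    class: sklearn.linear_model.LogisticRegression
    stochastic: false
    params:
      max_iter: 1000
  2:
    name: knn
    class: sklearn.neighbors.KNeighborsClassifier
    stochastic: false
    params:
      n_neighbors: 5
  3:
    name: svm_linear
    class: sklearn.svm.SVC
    stochastic: false
    params:
      kernel: linear
      max_iter: 100000
  4:
    name: svm_rbf
    class: sklearn.svm.SVC
    stochastic: false
    params:
      kernel: rbf
      max_iter: 100000
  5:
    name: decision_tree
    class: sklearn.tree.DecisionTreeClassifier
    stochastic: true
    params: {}
  6:
    name: random_forest
    class: sklearn.ensemble.RandomForestClassifier
    stochastic: true
    params:
      n_estimators: 100
  7:
    name: gradient_tree_boosting
    class: xgboost.XGBClassifier
    stochastic: true
    params:
      n_estimators: 100
      eval_metric: logloss
      verbosity: 0
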